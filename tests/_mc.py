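"""Monte-Carlo single-neuron oracle: plain Euler integration of the
diffusion-driven IF neuron (instantaneous synapses), independent of the
package's gain-function implementations.

The discrete-time scheme misses sub-step threshold excursions; the standard
first-passage correction (Gobet/Giles) lowers the tested threshold by
0.5826 * sigma_step to compensate, keeping the bias well below the
statistical error at the step sizes used here. The reflecting barrier is
implemented by mirroring."""

from __future__ import annotations

import numpy as np

_BOUNDARY_C = 0.5826  # zeta(1/2)/sqrt(2pi) first-passage correction


def mc_rate(
    mu: float,
    sigma2: float,
    model,
    dt: float = 0.01,
    n_neurons: int = 400,
    T: float = 2500.0,
    burn: float = 300.0,
    seed: int = 0,
):
    """Monte-Carlo stationary rate (Hz) and its standard error.

    ``model`` is a spikefp NeuronModel; mu/sigma2 are the total input
    moments in the model's units (mV, mV^2; v_thr/ms units for VIF)."""
    rng = np.random.default_rng(seed)
    tau_m = model.tau_m
    sig_step = np.sqrt(sigma2 * dt / tau_m)
    v_cut = model.spike_cutoff() - _BOUNDARY_C * sig_step
    v_lo = model.lower_barrier(np.sqrt(max(sigma2, 1e-12)), mu)
    steps = int(round(T / dt))
    burn_steps = int(round(burn / dt))
    ref_steps = int(round(model.tau_ref / dt))

    V = rng.uniform(model.v_res, model.v_thr, n_neurons)
    refr = np.zeros(n_neurons, dtype=int)
    counts = np.zeros(n_neurons, dtype=np.int64)

    kind = model.kind
    for t in range(steps):
        active = refr == 0
        fv = model.f(V)
        V = np.where(
            active,
            V + dt * (mu - fv) / tau_m + sig_step * rng.standard_normal(n_neurons),
            V,
        )
        refr[~active] -= 1
        # reflecting barrier (mirror)
        below = V < v_lo
        if below.any():
            V[below] = 2.0 * v_lo - V[below]
        spk = active & (V >= v_cut)
        if spk.any():
            V[spk] = model.v_res
            refr[spk] = ref_steps
            if t >= burn_steps:
                counts[spk] += 1
    T_eff = (steps - burn_steps) * dt * 1e-3  # s
    rates = counts / T_eff
    rate = float(rates.mean())
    se = float(rates.std(ddof=1) / np.sqrt(n_neurons))
    return rate, se
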