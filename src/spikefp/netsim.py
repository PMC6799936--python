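"""Clock-driven microscopic simulation of recurrent IF networks.

Transmission protocols per projection:

``delays``
    instantaneous (delta) synapses; each presynaptic spike adds J (mV) to the
    target potential after an axonal delay drawn from the projection's delay
    kernel (clipped so the minimum is delta_min + dt).
``filter``
    first-order synaptic filtering: each spike adds tau_m*J/tau_s (mV) to a
    per-neuron current variable u (voltage units, u = R*I) decaying with
    tau_s, delivered after the fixed minimum delay; the time-integral of the
    induced PSP equals J*tau_m, as for a delta synapse (the J -> J/tau_s
    rescaling).
``cascade``
    both: filtered synapses with distributed axonal delays.

External drive per population is either explicit Poisson spike trains
through delta synapses of efficacy J_ext, or the diffusion-equivalent
Gaussian current with matched moments. Integration is forward Euler at a
fixed step dt (default 0.05 ms); spike effects are aligned to the grid step
following the arrival time (rounding up). All randomness comes from a single
seeded generator, so identical spec + seed gives identical spike output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from numba import njit

from .delays import DelayKernel
from .meanfield import SynapticConfig, external_moments
from .models import EIF, LIF, VIF, NeuronModel, lif_neuron

__all__ = [
    "Population",
    "Projection",
    "NetworkSpec",
    "SimOutput",
    "sample_delays",
    "simulate",
    "single_population_spec",
    "build_multimodular",
]

_KIND_CODE = {VIF: 0, LIF: 1, EIF: 2}
_MODE_DELAYS, _MODE_FILTER, _MODE_CASCADE = 0, 1, 2
_MODE_CODE = {"delays": _MODE_DELAYS, "filter": _MODE_FILTER, "cascade": _MODE_CASCADE}


@dataclass(frozen=True)
class Population:
    label: str
    N: int
    model: NeuronModel
    C_ext: float = 0.0
    nu_ext: float = 0.0  # Hz per source
    J_ext: float = 0.0  # mV
    I_DC: float = 0.0  # pA (v_thr/ms for VIF)
    sigma_ext: float = 0.0  # explicit white noise (mV)
    poisson_ext: bool = True  # False -> diffusion-equivalent Gaussian drive
    tau_s: float = 0.0  # synaptic filter constant for afferent filtered input


@dataclass(frozen=True)
class Projection:
    source: str
    target: str
    C: int  # fixed in-degree per target neuron
    J: float  # efficacy (mV)
    mode: str = "delays"  # delays | filter | cascade
    kernel: DelayKernel = field(default_factory=DelayKernel.none)
    delta_min: float = 0.0  # ms

    def __post_init__(self) -> None:
        if self.mode not in _MODE_CODE:
            raise ValueError(f"unknown transmission mode {self.mode!r}")


@dataclass(frozen=True)
class NetworkSpec:
    populations: Tuple[Population, ...]
    projections: Tuple[Projection, ...] = ()
    dt: float = 0.05  # ms
    seed: int = 0
    rate_bin: float = 0.1  # ms, population-rate binning
    n_tagged: int = 0  # record (V, u) for the first n_tagged neurons per pop
    tag_stride: int = 20  # record every tag_stride-th step
    store_spikes: bool = True

    def pop_index(self, label: str) -> int:
        for i, p in enumerate(self.populations):
            if p.label == label:
                return i
        raise KeyError(label)

    def to_json(self) -> str:
        import json
        from dataclasses import asdict

        d = asdict(self)
        for p, pd in zip(self.populations, d["populations"]):
            pd["model"] = p.model.to_dict()
        for pr, prd in zip(self.projections, d["projections"]):
            prd["kernel"] = pr.kernel.to_dict()
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, s: str) -> "NetworkSpec":
        import json

        d = json.loads(s)
        pops = []
        for pd in d.pop("populations"):
            pd["model"] = NeuronModel.from_dict(pd["model"])
            pops.append(Population(**pd))
        projs = []
        for prd in d.pop("projections"):
            prd["kernel"] = DelayKernel.from_dict(prd["kernel"])
            projs.append(Projection(**prd))
        return cls(populations=tuple(pops), projections=tuple(projs), **d)


@dataclass
class SimOutput:
    spikes: Optional[np.ndarray]  # (n_spikes, 2): time ms, neuron id
    t_bins: np.ndarray  # bin centers (ms)
    nu: np.ndarray  # (n_bins, n_pops) population rate (Hz)
    pop_slices: List[slice]
    labels: List[str]
    tagged_t: Optional[np.ndarray] = None
    tagged_V: Optional[np.ndarray] = None  # (n_samples, n_tagged_total)
    tagged_u: Optional[np.ndarray] = None  # filtered synaptic input (mV)
    tagged_ids: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def mean_rate(self, pop: int = 0, discard: float = 1000.0) -> float:
        m = self.t_bins >= discard
        return float(self.nu[m, pop].mean())


def sample_delays(
    kernel: DelayKernel, delta_min: float, dt: float, n: int,
    seed_or_rng,
) -> np.ndarray:
    """n i.i.d. transmission delays (ms) with minimum delta_min + dt."""
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    return kernel.sample(n, rng, low=delta_min + dt)


# ---------------------------------------------------------------------------


@njit(cache=True)
def _poisson_small(lam: float) -> int:
    # inversion sampling, efficient for the small rates per step used here
    L = np.exp(-lam)
    k = 0
    p = 1.0
    while True:
        p *= np.random.random()
        if p <= L:
            return k
        k += 1


@njit(cache=True)
def _run_core(
    steps, dt, seed, B,
    kind, tau_m, v_thr, v_res, v_min, E_L, Delta_T, V_peak, ref_steps,
    tau_s_n, mu_dc, sig_step, lam_poisson, J_ext_jump,
    indptr, tgt, dstep, wgt, is_filt,
    delta_buf, filt_buf,
    V, u, pop_of, n_pops, bin_steps,
    spike_t, spike_id, max_spikes,
    nu_counts,
    n_tag, tag_stride, tag_V, tag_u,
    drive_mod,
):
    np.random.seed(seed)
    n = V.size
    refr = np.zeros(n, dtype=np.int64)
    n_spk = 0
    for t in range(steps):
        slot = t % B
        b = t // bin_steps
        mod = drive_mod[t]
        for i in range(n):
            # synaptic filter state always integrates
            if tau_s_n[i] > 0.0:
                u[i] += dt * (-u[i]) / tau_s_n[i] + filt_buf[slot, i]
            if refr[i] > 0:
                refr[i] -= 1
                V[i] = v_res[i]
                continue
            # leak drift
            if kind[i] == 0:
                fv = 0.0
            elif kind[i] == 1:
                fv = V[i] - E_L[i]
            else:
                ex = (V[i] - v_thr[i]) / Delta_T[i]
                if ex > 500.0:
                    ex = 500.0
                fv = (V[i] - E_L[i]) - Delta_T[i] * np.exp(ex)
            dV = dt * (-fv + u[i] + mu_dc[i]) / tau_m[i]
            if sig_step[i] > 0.0:
                dV += sig_step[i] * np.random.normal()
            # external Poisson delta input
            if lam_poisson[i] > 0.0:
                kk = _poisson_small(lam_poisson[i] * mod)
                if kk > 0:
                    dV += kk * J_ext_jump[i]
            V[i] += dV + delta_buf[slot, i]
            if V[i] < v_min[i]:
                V[i] = v_min[i]
            thr = V_peak[i] if kind[i] == 2 else v_thr[i]
            if V[i] >= thr:
                # spike
                if n_spk < max_spikes:
                    spike_t[n_spk] = t * dt
                    spike_id[n_spk] = i
                n_spk += 1
                nu_counts[b, pop_of[i]] += 1.0
                V[i] = v_res[i]
                refr[i] = ref_steps[i]
                for e in range(indptr[i], indptr[i + 1]):
                    sl = (t + dstep[e]) % B
                    if is_filt[e] == 1:
                        filt_buf[sl, tgt[e]] += wgt[e]
                    else:
                        delta_buf[sl, tgt[e]] += wgt[e]
        # clear the consumed slot
        for i in range(n):
            delta_buf[slot, i] = 0.0
            filt_buf[slot, i] = 0.0
        if n_tag > 0 and t % tag_stride == 0:
            r = t // tag_stride
            for j in range(n_tag):
                tag_V[r, j] = V[j]
                tag_u[r, j] = u[j]
    return n_spk


def simulate(spec: NetworkSpec, T: float,
             drive: Optional[callable] = None) -> SimOutput:
    """Run the network for T ms and return spikes + binned population rates.

    ``drive(t_ms)`` optionally modulates the external Poisson rate
    multiplicatively (relative to the configured nu_ext) for all
    populations; requires poisson_ext drive."""
    if T <= 0:
        raise ValueError("T must be positive")
    dt = spec.dt
    pops = spec.populations
    if any(p.N <= 0 for p in pops):
        raise ValueError("empty population")
    n_pops = len(pops)
    offs = np.cumsum([0] + [p.N for p in pops])
    n = int(offs[-1])
    pop_slices = [slice(int(offs[i]), int(offs[i + 1])) for i in range(n_pops)]

    rng = np.random.default_rng(spec.seed)

    def per_neuron(fn):
        return np.concatenate([np.full(p.N, fn(p)) for p in pops])

    kind = per_neuron(lambda p: _KIND_CODE[p.model.kind]).astype(np.int64)
    tau_m = per_neuron(lambda p: p.model.tau_m)
    v_thr = per_neuron(lambda p: p.model.v_thr)
    v_res = per_neuron(lambda p: p.model.v_res)
    E_L = per_neuron(lambda p: p.model.E_L)
    Delta_T = per_neuron(lambda p: p.model.Delta_T or 1.0)
    V_peak = per_neuron(lambda p: p.model.V_peak or p.model.v_thr)
    ref_steps = per_neuron(lambda p: int(round(p.model.tau_ref / dt))).astype(np.int64)
    tau_s_n = per_neuron(lambda p: p.tau_s)

    # external drive
    mu_dc = np.zeros(n)
    sig_step = np.zeros(n)
    lam_poisson = np.zeros(n)
    J_ext_jump = np.zeros(n)
    v_min = np.zeros(n)
    for p, sl in zip(pops, pop_slices):
        m = p.model
        mu_dc[sl] = m.R * p.I_DC
        rate_ms = p.C_ext * p.nu_ext * 1e-3
        s2_white = p.sigma_ext**2
        if p.poisson_ext:
            lam_poisson[sl] = rate_ms * dt
            J_ext_jump[sl] = p.J_ext
            s2_ext = 0.0
        else:
            mu_dc[sl] += m.tau_m * p.J_ext * rate_ms
            s2_ext = m.tau_m * p.J_ext**2 * rate_ms
        s2_tot = s2_white + s2_ext
        sig_step[sl] = np.sqrt(s2_tot * dt / m.tau_m) if s2_tot > 0 else 0.0
        # reflecting barrier: hard 0 for VIF, wide for LIF/EIF
        sig_est = np.sqrt(max(s2_white + m.tau_m * p.J_ext**2 * rate_ms, 1e-6))
        v_min[sl] = m.lower_barrier(sig_est)

    # connectivity: fixed in-degree per target, CSR by source neuron
    src_list, tgt_list, d_list, w_list, filt_list = [], [], [], [], []
    for proj in spec.projections:
        si = spec.pop_index(proj.source)
        ti = spec.pop_index(proj.target)
        s0, s1 = offs[si], offs[si + 1]
        mode = _MODE_CODE[proj.mode]
        srcpop = pops[si]
        tgtpop = pops[ti]
        for j in range(offs[ti], offs[ti + 1]):
            if proj.C == 0:
                continue
            pres = rng.choice(np.arange(s0, s1), size=proj.C, replace=False)
            if mode == _MODE_DELAYS:
                dl = sample_delays(proj.kernel, proj.delta_min, dt, proj.C, rng)
                w = np.full(proj.C, proj.J)
                is_f = np.zeros(proj.C, dtype=np.int64)
            else:
                tau_s = tgtpop.tau_s
                if tau_s <= 0:
                    raise ValueError(
                        f"projection {proj.source}->{proj.target} is filtered "
                        "but target population has tau_s = 0"
                    )
                if mode == _MODE_FILTER:
                    dl = np.full(proj.C, proj.delta_min + dt)
                else:  # cascade: filter + distributed delays
                    dl = sample_delays(proj.kernel, proj.delta_min, dt, proj.C, rng)
                w = np.full(proj.C, tgtpop.model.tau_m * proj.J / tau_s)
                is_f = np.ones(proj.C, dtype=np.int64)
            src_list.append(pres)
            tgt_list.append(np.full(proj.C, j, dtype=np.int64))
            d_list.append(np.ceil(dl / dt).astype(np.int64))
            w_list.append(w)
            filt_list.append(is_f)
    if src_list:
        src = np.concatenate(src_list)
        order = np.argsort(src, kind="stable")
        src = src[order]
        tgt = np.concatenate(tgt_list)[order]
        dstep = np.concatenate(d_list)[order]
        wgt = np.concatenate(w_list)[order]
        is_filt = np.concatenate(filt_list)[order]
        indptr = np.searchsorted(src, np.arange(n + 1))
    else:
        tgt = np.zeros(0, dtype=np.int64)
        dstep = np.zeros(0, dtype=np.int64)
        wgt = np.zeros(0)
        is_filt = np.zeros(0, dtype=np.int64)
        indptr = np.zeros(n + 1, dtype=np.int64)

    B = int(dstep.max()) + 2 if dstep.size else 2
    delta_buf = np.zeros((B, n))
    filt_buf = np.zeros((B, n))

    steps = int(round(T / dt))
    bin_steps = max(int(round(spec.rate_bin / dt)), 1)
    n_bins = steps // bin_steps + 1
    nu_counts = np.zeros((n_bins, n_pops))

    # initial state: V uniform in [v_res, v_thr) to shorten transients
    V = np.empty(n)
    for p, sl in zip(pops, pop_slices):
        V[sl] = rng.uniform(p.model.v_res, p.model.v_thr, p.N)
    u = np.zeros(n)

    max_spikes = int(min(n * T * 0.4 + 1e5, 4e7))  # cap at ~400 Hz mean
    spike_t = np.zeros(max_spikes)
    spike_id = np.zeros(max_spikes, dtype=np.int64)

    n_tag = min(spec.n_tagged, n)
    n_rec = steps // spec.tag_stride + 1 if n_tag else 1
    tag_V = np.zeros((n_rec, max(n_tag, 1)))
    tag_u = np.zeros((n_rec, max(n_tag, 1)))

    if drive is not None:
        if any(not p.poisson_ext and p.C_ext for p in pops):
            raise ValueError("time-varying drive requires poisson_ext external input")
        drive_mod = np.array([drive(t * dt) for t in range(steps)], dtype=float)
    else:
        drive_mod = np.ones(steps)

    core_seed = int(rng.integers(0, 2**31 - 1))
    n_spk = _run_core(
        steps, dt, core_seed, B,
        kind, tau_m, v_thr, v_res, v_min, E_L, Delta_T, V_peak, ref_steps,
        tau_s_n, mu_dc, sig_step, lam_poisson, J_ext_jump,
        indptr.astype(np.int64), tgt, dstep, wgt, is_filt,
        delta_buf, filt_buf,
        V, u, np.repeat(np.arange(n_pops), [p.N for p in pops]).astype(np.int64),
        n_pops, bin_steps,
        spike_t, spike_id, max_spikes,
        nu_counts,
        n_tag, spec.tag_stride, tag_V, tag_u,
        drive_mod,
    )
    kept = min(n_spk, max_spikes)
    spikes = None
    if spec.store_spikes:
        spikes = np.column_stack([spike_t[:kept], spike_id[:kept].astype(float)])

    n_full = steps // bin_steps
    t_bins = (np.arange(n_full) + 0.5) * bin_steps * dt
    Ns = np.array([p.N for p in pops], dtype=float)
    nu = nu_counts[:n_full] / (Ns[None, :] * bin_steps * dt * 1e-3)

    out = SimOutput(
        spikes=spikes,
        t_bins=t_bins,
        nu=nu,
        pop_slices=pop_slices,
        labels=[p.label for p in pops],
        meta={"dt": dt, "seed": spec.seed, "T": T, "n_spikes": int(n_spk),
              "N": [p.N for p in pops]},
    )
    if n_tag:
        out.tagged_t = np.arange(n_rec) * spec.tag_stride * dt
        out.tagged_V = tag_V
        out.tagged_u = tag_u
        out.tagged_ids = np.arange(n_tag)
    return out


# ---------------------------------------------------------------------------


def single_population_spec(
    config: SynapticConfig,
    model: NeuronModel,
    N: Optional[int] = None,
    protocol: str = "delays",
    tau: float = 0.0,
    dt: float = 0.05,
    seed: int = 0,
    poisson_ext: bool = True,
    **kw,
) -> NetworkSpec:
    """One excitatory population from a mean-field configuration.

    ``protocol`` = 'delays' (exponential delay kernel with decay ``tau`` on
    top of delta_min), 'filter' (synaptic time constant ``tau``), or
    'cascade'. tau = 0 gives instantaneous transmission at the minimum delay
    in every protocol."""
    N = N or config.N
    if tau == 0.0:
        protocol = "delays"  # instantaneous limit is common to all protocols
    kernel = (DelayKernel.exponential(tau) if tau > 0 else DelayKernel.none())
    nu_ext = config.nu_ext if config.C_ext else 0.0
    pop = Population(
        label="E", N=N, model=model,
        C_ext=config.C_ext, nu_ext=nu_ext, J_ext=config.J_ext,
        I_DC=config.I_DC, sigma_ext=config.sigma_ext,
        poisson_ext=poisson_ext,
        tau_s=(tau if protocol in ("filter", "cascade") else 0.0),
    )
    proj = Projection(
        source="E", target="E", C=int(config.C), J=config.J,
        mode=protocol,
        kernel=(kernel if protocol in ("delays", "cascade") else DelayKernel.none()),
        delta_min=config.delta_min,
    )
    return NetworkSpec(populations=(pop,), projections=(proj,), dt=dt,
                       seed=seed, **kw)


def multimodular_J_ext(c_alpha_I: float) -> float:
    """External/recurrent excitatory efficacy (mV) keeping the 10-Hz
    equilibrium as the inhibitory connection percentage c_alpha_I grows."""
    return (9.56e-5 * c_alpha_I + 0.0234) * c_alpha_I + 0.0485


def build_multimodular(
    c_alpha_I: float,
    tau: float = 4.0,
    protocol: str = "filter",
    N_E: int = 4000,
    N_I: int = 1000,
    C_ext: int = 1800,
    nu_ext: float = 10.0,
    J_I: float = -0.05,
    c_E: float = 5.0,
    dt: float = 0.05,
    delta_min: float = 3.0,
    seed: int = 0,
    J_ext: Optional[float] = None,
    ext_fraction: Optional[float] = None,
    **kw,
) -> NetworkSpec:
    """Two-population (E-I) LIF network with inhibition percentage
    ``c_alpha_I`` (percent of N_I).

    Recurrent excitatory in-degree C_EE = C_IE = c_E% of N_E replaces an
    equal number of external contacts; J_ext follows the printed quadratic
    in c_alpha_I unless given. ``ext_fraction``, if given, sets the balance
    C_I,ext/(C_IE + C_I,ext) for the inhibitory population at fixed total
    excitatory in-degree (the exchange variant)."""
    if not 0.0 <= c_alpha_I <= 100.0:
        raise ValueError("c_alpha_I is a percentage in [0, 100]")
    model = lif_neuron(tau_m=20.0, C_m=100.0, v_thr=20.0, v_res=10.0,
                       E_L=0.0, tau_ref=0.0)
    Jx = J_ext if J_ext is not None else multimodular_J_ext(c_alpha_I)
    C_I = int(round(c_alpha_I / 100.0 * N_I))
    C_E = int(round(c_E / 100.0 * N_E))
    C_E_ext = max(C_ext - C_E, 0)
    C_IE, C_I_ext = C_E, C_E_ext
    if ext_fraction is not None:
        tot = C_ext
        C_I_ext = int(round(ext_fraction * tot))
        C_IE = tot - C_I_ext
    kernel = DelayKernel.exponential(tau) if tau > 0 else DelayKernel.none()
    use_filter = protocol in ("filter", "cascade")
    pk = kernel if protocol in ("delays", "cascade") else DelayKernel.none()
    pops = (
        Population("E", N_E, model, C_ext=C_E_ext, nu_ext=nu_ext, J_ext=Jx,
                   poisson_ext=True, tau_s=(tau if use_filter else 0.0)),
        Population("I", N_I, model, C_ext=C_I_ext, nu_ext=nu_ext, J_ext=Jx,
                   poisson_ext=True, tau_s=(tau if use_filter else 0.0)),
    )
    projs = []
    for tgt_lab, cee in (("E", C_E), ("I", C_IE)):
        if cee:
            projs.append(Projection("E", tgt_lab, C=cee, J=Jx, mode=protocol,
                                    kernel=pk, delta_min=delta_min))
    for tgt_lab in ("E", "I"):
        if C_I:
            projs.append(Projection("I", tgt_lab, C=C_I, J=J_I, mode=protocol,
                                    kernel=pk, delta_min=delta_min))
    return NetworkSpec(populations=pops, projections=tuple(projs), dt=dt,
                       seed=seed, **kw)
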