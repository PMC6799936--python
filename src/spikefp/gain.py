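"""Stationary input-output gain functions Phi(mu, sigma) under the diffusion
approximation, and their gradients.

The gain function is the stationary escape rate of the drift-diffusion
process  tau_m dV = (mu - f(V)) dt + sigma sqrt(tau_m) dW  between the
reflecting lower barrier and the absorbing threshold, with reinjection at the
reset potential and an absolute refractory period added to the inter-spike
interval.

* LIF: Siegert formula, numerically stabilised through erfcx.
* VIF: closed form of the stationary flux problem on [0, 1] with reflecting
  barrier at 0 (derived by solving mu rho - (sigma^2/2) rho' = nu with
  rho(1) = 0 and unit mass).
* EIF: steady-state threshold integration (backward flux integration from
  V_peak), no closed form exists.
"""

from __future__ import annotations

import warnings
from typing import Tuple

import numpy as np
from scipy.integrate import quad
from scipy.special import erfcx

from .models import EIF, LIF, VIF, InputMoments, NeuronModel

__all__ = [
    "siegert_rate_lif",
    "vif_rate",
    "vif_rate_gradient",
    "eif_rate",
    "rate",
    "gain_gradient",
]

#: rates below this (Hz) are treated as numerical zero by gain_gradient
UNDERFLOW_RATE_HZ = 1e-12


def _require_kind(model: NeuronModel, kind: str) -> None:
    if model.kind != kind:
        raise ValueError(f"model mismatch: expected {kind}, got {model.kind}")


def siegert_rate_lif(moments: InputMoments, model: NeuronModel) -> float:
    """Stationary firing rate (Hz) of the LIF diffusion.

    1/Phi = tau_ref + tau_m sqrt(pi) * int_{(v_res-E_L-mu)/sigma}^{(v_thr-E_L-mu)/sigma}
            erfcx(-u) du,
    where erfcx(-u) = e^{u^2}(1 + erf(u)).
    """
    _require_kind(model, LIF)
    if moments.sigma2 <= 0:
        raise ValueError(
            "siegert_rate_lif requires sigma2 > 0; for the noiseless limit use "
            "the closed form 1/(tau_m*ln((mu-v_res)/(mu-v_thr))) for mu > v_thr"
        )
    sigma = moments.sigma
    a = (model.v_res - model.E_L - moments.mu) / sigma
    b = (model.v_thr - model.E_L - moments.mu) / sigma
    if b > 26.0:
        # deep subthreshold: the integrand e^{u^2} overflows in double
        # precision; integrate in extended precision (mpmath ships with sympy)
        import mpmath as mp

        integral = float(
            mp.quad(lambda u: mp.exp(u * u) * mp.erfc(-u), [a, min(b, 40.0)])
        )
        if not np.isfinite(integral):
            return 0.0
    else:
        integral, _ = quad(lambda u: erfcx(-u), a, b, epsabs=1e-10, limit=200)
    isi_ms = model.tau_ref + model.tau_m * np.sqrt(np.pi) * integral
    return 1000.0 / isi_ms


def lif_noiseless_rate(mu: float, model: NeuronModel) -> float:
    """Deterministic LIF rate (Hz) for sigma = 0 and mu > v_thr - E_L."""
    _require_kind(model, LIF)
    drive = mu + model.E_L
    if drive <= model.v_thr:
        return 0.0
    isi = model.tau_ref + model.tau_m * np.log(
        (drive - model.v_res) / (drive - model.v_thr)
    )
    return 1000.0 / isi


def _vif_denominator(t: float) -> float:
    """d(t) = 1 - (1 - e^{-t})/t with t = 2 mu / sigma^2, series-safe."""
    if abs(t) < 1e-8:
        return t / 2.0 - t * t / 6.0
    if t < -500.0:
        # e^{-t} overflows; d ~ e^{-t}/t dominates
        return np.inf
    return 1.0 + np.expm1(-t) / t


def vif_rate(moments: InputMoments, model: NeuronModel) -> float:
    """Stationary rate (Hz) of the VIF neuron (constant drift on [0, 1],
    reflecting barrier at 0, absorbing at 1, reinjection at 0).

    nu = mu / [1 - (sigma^2 / 2 mu)(1 - e^{-2 mu / sigma^2})]   (1/ms)

    Positive for sigma^2 > 0 even when the drift is negative: escapes are then
    sustained by diffusion against the reflecting barrier.
    """
    _require_kind(model, VIF)
    mu, s2 = moments.mu, moments.sigma2
    if s2 == 0.0:
        nu_ms = max(mu, 0.0) / model.v_thr
    else:
        t = 2.0 * mu / s2
        if t < -500.0:
            nu_ms = mu * t * np.exp(t)  # -> 0+ for strongly negative drift
        elif abs(t) < 1e-8:
            nu_ms = s2 / 2.0 * 2.0 / (1.0 - t / 3.0)  # series of mu/d(t)
        else:
            nu_ms = mu / _vif_denominator(t)
    if model.tau_ref > 0.0 and nu_ms > 0.0:
        nu_ms = 1.0 / (1.0 / nu_ms + model.tau_ref)
    return 1000.0 * nu_ms


def vif_rate_gradient(moments: InputMoments, model: NeuronModel) -> Tuple[float, float]:
    """Analytic (d nu/d mu, d nu/d sigma^2) of the VIF closed form, in
    Hz/(v_thr/ms) and Hz/(v_thr^2/ms)."""
    _require_kind(model, VIF)
    if model.tau_ref != 0.0:
        raise NotImplementedError("analytic VIF gradient assumes tau_ref = 0")
    mu, s2 = moments.mu, moments.sigma2
    D = s2 / 2.0
    t = mu / D
    d = _vif_denominator(2.0 * mu / s2)  # = 1 + expm1(-t)/t
    # dd/dt = (-t e^{-t} - expm1(-t)) / t^2
    ddt = (-t * np.exp(-t) - np.expm1(-t)) / (t * t)
    dnu_dmu = 1.0 / d - (mu / d**2) * ddt / D
    dnu_ds2 = (mu * t * ddt) / (2.0 * D * d**2)
    return 1000.0 * dnu_dmu, 1000.0 * dnu_ds2


def eif_rate(moments: InputMoments, model: NeuronModel, dv: float = 0.01) -> float:
    """Stationary rate (Hz) of the EIF by backward threshold integration.

    Integrates the steady-state flux relation
    (sigma^2/2) p' = G(V) p - tau_m F(V),  G = mu + E_L - V + Delta_T e^{(V-v_thr)/Delta_T},
    from V_peak (p = 0) down to the reflecting barrier, with unit flux above
    v_res and zero below; the rate is 1/(tau_ref + integral of p).
    """
    _require_kind(model, EIF)
    if moments.sigma2 <= 0:
        raise ValueError("eif_rate requires sigma2 > 0")
    mu, s2 = moments.mu, moments.sigma2
    sigma = np.sqrt(s2)
    v_lo = model.lower_barrier(sigma, mu)
    v_hi = model.V_peak
    n = max(int(np.ceil((v_hi - v_lo) / dv)), 64)
    grid = np.linspace(v_lo, v_hi, n + 1)
    step = grid[1] - grid[0]
    G = mu + model.E_L - grid + model.Delta_T * np.exp(
        np.minimum((grid - model.v_thr) / model.Delta_T, 500.0)
    )
    a = 2.0 * G / s2  # 1/mV
    p = 0.0
    integral = 0.0  # int p dV, equals the mean ISI (ms) for unit flux
    for k in range(n, 0, -1):
        ak = a[k]
        b = (2.0 * model.tau_m / s2) if grid[k] > model.v_res else 0.0
        if abs(ak) * step < 1e-12:
            p_new = p + b * step
        else:
            r = b / ak
            p_new = (p - r) * np.exp(-ak * step) + r
        p = max(p_new, 0.0)
        integral += p * step
        if integral > 1e250:
            # quiescent regime: rate numerically zero
            return 1000.0 / (model.tau_ref + integral)
    return 1000.0 / (model.tau_ref + integral)


def rate(moments: InputMoments, model: NeuronModel, **kw) -> float:
    """Gain function Phi(mu, sigma) (Hz), dispatched on the model kind."""
    if model.kind == LIF:
        if moments.sigma2 <= 0:
            return lif_noiseless_rate(moments.mu, model)
        return siegert_rate_lif(moments, model)
    if model.kind == VIF:
        return vif_rate(moments, model)
    return eif_rate(moments, model, **kw)


def gain_gradient(
    moments: InputMoments,
    model: NeuronModel,
    rel_step: float = 1e-4,
) -> Tuple[float, float, bool]:
    """Central finite differences (dPhi/dmu, dPhi/dsigma2) of the gain
    function; returns (d_mu, d_sigma2, ok). When Phi underflows at the
    evaluation point both components are 0 and ok is False."""
    phi0 = rate(moments, model)
    if not np.isfinite(phi0) or phi0 < UNDERFLOW_RATE_HZ:
        return 0.0, 0.0, False
    scale_mu = max(abs(moments.mu), model.v_thr - model.v_res)
    h_mu = rel_step * scale_mu
    h_s2 = rel_step * max(moments.sigma2, 1e-6)
    d_mu = (
        rate(InputMoments(moments.mu + h_mu, moments.sigma2), model)
        - rate(InputMoments(moments.mu - h_mu, moments.sigma2), model)
    ) / (2 * h_mu)
    s2_lo = max(moments.sigma2 - h_s2, 1e-12)
    d_s2 = (
        rate(InputMoments(moments.mu + 0.0, moments.sigma2 + h_s2), model)
        - rate(InputMoments(moments.mu, s2_lo), model)
    ) / (moments.sigma2 + h_s2 - s2_lo)
    if not (np.isfinite(d_mu) and np.isfinite(d_s2)):
        warnings.warn("non-finite gain gradient; returning zeros")
        return 0.0, 0.0, False
    return float(d_mu), float(d_s2), True
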