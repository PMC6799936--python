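"""Mean-field mapping from network configuration to input moments, fixed
points of the population rate, and the parameter-identification recipe.

Under the extended mean-field approximation every neuron receives recurrent
input with infinitesimal moments

    mu_I(nu)     = tau_m * J * C * nu
    sigma_I^2(nu)= tau_m * J^2 * C * nu

(nu in 1/ms internally; the public API uses Hz), plus an external Poissonian
drive with efficacy J_ext from C_ext sources at rate nu_ext, a DC bias I_DC
and optionally an explicit white-noise current of amplitude sigma_ext.
For the VIF model tau_m = 1 ms and C_m = 1 by convention, so the same
formulae hold with J in threshold units and I_DC in v_thr/ms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .delays import DelayKernel
from .gain import gain_gradient, rate
from .models import VIF, InputMoments, NeuronModel

__all__ = [
    "SynapticConfig",
    "recurrent_moments",
    "external_moments",
    "total_moments",
    "FixedPoint",
    "self_consistent_rate",
    "identify_parameters",
    "NoFixedPointError",
]


@dataclass(frozen=True)
class SynapticConfig:
    """Connectivity, efficacies, transmission protocol and external drive of a
    (single-population view of a) recurrent network."""

    N: int = 0  # neuron count (0 = infinite / not used)
    C: float = 0.0  # mean recurrent in-degree
    J: float = 0.0  # recurrent efficacy (mV delta-PSP; v_thr units for VIF)
    tau_s: float = 0.0  # synaptic filter time constant (ms; 0 = instantaneous)
    delay_kernel: Optional[DelayKernel] = None
    delta_min: float = 0.0  # minimum transmission delay (ms)
    J_ext: float = 0.0  # external efficacy (mV)
    C_ext: float = 0.0  # external in-degree
    nu_ext: float = 0.0  # external per-source rate (Hz)
    I_DC: float = 0.0  # bias current (pA; v_thr/ms for VIF)
    sigma_ext: float = 0.0  # explicit white-noise amplitude (mV / sqrt(ms))

    def __post_init__(self) -> None:
        if self.N and self.C > self.N:
            raise ValueError("in-degree C cannot exceed N")
        if self.C < 0 or self.tau_s < 0 or self.delta_min < 0 or self.nu_ext < 0:
            raise ValueError("C, tau_s, delta_min and nu_ext must be nonnegative")

    @property
    def C_ext_nu_ext(self) -> float:
        """Total external spike rate C_ext * nu_ext (Hz)."""
        return self.C_ext * self.nu_ext

    def to_json(self) -> str:
        d = asdict(self)
        if self.delay_kernel is not None:
            d["delay_kernel"] = self.delay_kernel.to_dict()
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, s: str) -> "SynapticConfig":
        d = json.loads(s)
        if d.get("delay_kernel") is not None:
            d["delay_kernel"] = DelayKernel.from_dict(d["delay_kernel"])
        return cls(**d)


def recurrent_moments(
    nu: float, config: SynapticConfig, model: NeuronModel
) -> Tuple[float, float]:
    """(mu_I, sigma_I^2) of the recurrent input at network rate ``nu`` (Hz).

    Both are exactly linear in nu. Units: mV and mV^2 (v_thr/ms and
    v_thr^2/ms for VIF, where tau_m = 1)."""
    nu_ms = nu * 1e-3
    mu_I = model.tau_m * config.J * config.C * nu_ms
    sigma_I2 = model.tau_m * config.J**2 * config.C * nu_ms
    return mu_I, sigma_I2


def external_moments(
    config: SynapticConfig, model: NeuronModel, dt: Optional[float] = None
) -> dict:
    """Moments of the external drive.

    Returns a dict with the voltage-equivalent moments used by the mean
    field (``mu_ext`` = tau_m J_ext C_ext nu_ext, ``sigma_ext2`` =
    tau_m J_ext^2 C_ext nu_ext, both including the 1e-3 Hz -> 1/ms
    rescaling) and, when ``dt`` is given, the moments of the equivalent
    Wiener current in pA / pA^2 (variance carrying the explicit 1/dt)."""
    rate_ms = config.C_ext_nu_ext * 1e-3
    out = {
        "mu_ext": model.tau_m * config.J_ext * rate_ms,
        "sigma_ext2": model.tau_m * config.J_ext**2 * rate_ms,
    }
    if dt is not None:
        out["mu_ext_current"] = model.C_m * config.J_ext * rate_ms
        out["sigma_ext2_current"] = (model.C_m * config.J_ext) ** 2 * rate_ms / dt
    return out


def total_moments(
    nu: float, config: SynapticConfig, model: NeuronModel
) -> InputMoments:
    """Total input moments at network rate nu (Hz):
    mu = mu_I + mu_ext + R I_DC, sigma^2 = sigma_I^2 + sigma_ext^2(Poisson)
    + sigma_ext^2 (explicit white noise)."""
    mu_I, s_I2 = recurrent_moments(nu, config, model)
    ext = external_moments(config, model)
    mu = mu_I + ext["mu_ext"] + model.R * config.I_DC
    sigma2 = s_I2 + ext["sigma_ext2"] + config.sigma_ext**2
    return InputMoments(mu, sigma2)


def transfer_rate(nu: float, config: SynapticConfig, model: NeuronModel) -> float:
    """Phi(total_moments(nu)) (Hz): one application of the mean-field map."""
    return rate(total_moments(nu, config, model), model)


@dataclass(frozen=True)
class FixedPoint:
    nu: float  # equilibrium rate (Hz)
    slope: float  # dPhi0/dnu at the fixed point (dimensionless)

    @property
    def stable(self) -> bool:
        return self.slope < 1.0


class NoFixedPointError(RuntimeError):
    def __init__(self, msg: str, nu_grid: np.ndarray, phi_grid: np.ndarray):
        super().__init__(msg)
        self.nu_grid = nu_grid
        self.phi_grid = phi_grid


def gain_slope(nu: float, config: SynapticConfig, model: NeuronModel) -> float:
    """dPhi0/dnu via the chain rule of Phi through (mu(nu), sigma^2(nu))."""
    m = total_moments(nu, config, model)
    d_mu, d_s2, ok = gain_gradient(m, model)
    if not ok:
        return 0.0
    dmu_dnu = model.tau_m * config.J * config.C * 1e-3
    ds2_dnu = model.tau_m * config.J**2 * config.C * 1e-3
    return d_mu * dmu_dnu + d_s2 * ds2_dnu


def self_consistent_rate(
    config: SynapticConfig,
    model: NeuronModel,
    bracket: Tuple[float, float] = (0.0, 200.0),
    n_scan: int = 400,
    tol: float = 1e-3,
) -> FixedPoint:
    """Fixed point of nu -> Phi(total_moments(nu)).

    The bracket is scanned for sign changes of Phi(nu) - nu; each is refined
    by bisection (brentq) to ``tol`` Hz. When multiple fixed points exist the
    stable one with the highest rate is returned; if none is stable, the
    highest-rate fixed point is returned with its slope."""
    if config.C == 0.0 or config.J == 0.0:
        nu = transfer_rate(0.0, config, model)
        return FixedPoint(nu=nu, slope=0.0)

    lo, hi = bracket
    nu_grid = np.linspace(max(lo, 0.0), hi, n_scan + 1)
    g = np.array([transfer_rate(v, config, model) - v for v in nu_grid])
    roots = []
    for i in range(n_scan):
        if g[i] == 0.0:
            roots.append(nu_grid[i])
        elif g[i] * g[i + 1] < 0:
            roots.append(
                brentq(
                    lambda v: transfer_rate(v, config, model) - v,
                    nu_grid[i],
                    nu_grid[i + 1],
                    xtol=tol,
                )
            )
    if not roots:
        raise NoFixedPointError(
            f"Phi(nu) - nu has no sign change in bracket {bracket}",
            nu_grid,
            g + nu_grid,
        )
    fps = [FixedPoint(nu=r, slope=gain_slope(r, config, model)) for r in sorted(roots)]
    stable = [fp for fp in fps if fp.stable]
    return stable[-1] if stable else fps[-1]


def identify_parameters(
    nu_star: float,
    slope: float,
    anchor: InputMoments,
    model: NeuronModel,
    C: float,
    C_ext_nu_ext: float,
) -> Tuple[float, float, float]:
    """Design (J, J_ext, I_DC) so that the network has a fixed point at
    ``nu_star`` (Hz) with gain slope dPhi0/dnu = ``slope`` there, and the
    total input moments at nu_star equal ``anchor``.

    The slope condition is a quadratic in J,
        slope = tau_m C [ J dPhi/dmu + J^2 dPhi/dsigma2 ] * 1e-3 ,
    whose root yielding a stable fixed point is taken (ties toward smaller
    |J|); (J_ext, I_DC) then follow in closed form from matching the anchor
    moments given the external spike rate C_ext_nu_ext (Hz)."""
    d_mu, d_s2, ok = gain_gradient(anchor, model)
    if not ok:
        raise ValueError("gain gradient underflows at the anchor point")
    k = model.tau_m * C * 1e-3
    if slope == 0.0:
        J = 0.0
    else:
        # d_s2 * J^2 + d_mu * J - slope/k = 0
        disc = d_mu**2 + 4.0 * d_s2 * slope / k
        if disc < 0:
            s_max = -k * d_mu**2 / (4.0 * d_s2) if d_s2 < 0 else np.inf
            raise ValueError(
                f"slope target {slope} infeasible at this anchor; attainable "
                f"slopes are below {s_max:.4g}"
            )
        if abs(d_s2) < 1e-300:
            roots = [slope / (k * d_mu)]
        else:
            sq = np.sqrt(disc)
            roots = [(-d_mu + sq) / (2 * d_s2), (-d_mu - sq) / (2 * d_s2)]
        # prefer roots giving a stable fixed point (slope < 1); ties -> small |J|
        stable_roots = [r for r in roots if slope < 1.0]
        cand = stable_roots if stable_roots else roots
        J = min(cand, key=abs)
    nu_ms = nu_star * 1e-3
    rext_ms = C_ext_nu_ext * 1e-3
    s2_rec = model.tau_m * J**2 * C * nu_ms
    s2_ext = anchor.sigma2 - s2_rec
    if s2_ext < 0:
        raise ValueError(
            f"anchor variance {anchor.sigma2:.4g} below recurrent contribution "
            f"{s2_rec:.4g}: J_ext^2 < 0 (infeasible)"
        )
    if rext_ms > 0:
        J_ext = float(np.sqrt(s2_ext / (model.tau_m * rext_ms)))
    else:
        if s2_ext > 1e-12:
            raise ValueError("anchor variance requires external spikes but C_ext*nu_ext = 0")
        J_ext = 0.0
    mu_rec = model.tau_m * J * C * nu_ms
    mu_ext = model.tau_m * J_ext * rext_ms
    I_DC = (anchor.mu - mu_rec - mu_ext) / model.R
    return float(J), J_ext, float(I_DC)
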