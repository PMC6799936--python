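"""Time integration of the one-dimensional Fokker-Planck equation with
low-pass-filtered feedback rate.

This is the reference reduced model for time-varying stimuli: the membrane
potential density rho_x(x, t) evolves under drift
(mu_I(nu_tilde) + mu_ext(t) - f(x))/tau_m and diffusion
(sigma_I^2(nu_tilde) + sigma_ext^2(t))/(2 tau_m), with the feedback rate
nu_tilde the exponentially smoothed (and minimum-delay shifted) version of
the threshold flux nu(t):

    tau_d d(nu_tilde)/dt = nu(t - delta_min) - nu_tilde .

Spatial discretization is the same mass-conserving Chang-Cooper
finite-volume scheme used for the spectral basis; time stepping is implicit
Euler in the diffusion/drift operator (unconditionally stable) with explicit
treatment of the reinjection source. Absorbed probability is reinjected at
v_res after the refractory transit tau_ref, so that total probability (grid
mass + in-transit mass) is conserved to machine precision at every step.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Optional, Tuple

import numpy as np
from scipy.linalg import solve_banded

from .meanfield import SynapticConfig, recurrent_moments, external_moments
from .models import InputMoments, NeuronModel
from .spectral import _assemble_operator, _face_flux_coeffs, SIGMA_EXT_FLOOR

__all__ = ["DensityTrajectory", "integrate_density", "stationary_density"]


def _banded_operator(
    grid: np.ndarray, dx: float, mu_tot: float, D: float, model: NeuronModel
) -> Tuple[np.ndarray, float]:
    """Tridiagonal FP operator (without reinjection) in solve_banded layout,
    plus the threshold flux coefficient."""
    n = grid.size
    faces = grid[:-1] + dx / 2.0
    v_face = (mu_tot - model.f(faces)) / model.tau_m
    cL, cR = _face_flux_coeffs(v_face, D, dx)
    v_thr_face = (mu_tot - model.f(np.array([model.v_thr]))[0]) / model.tau_m
    cT, _ = _face_flux_coeffs(np.array([v_thr_face]), D, dx / 2.0)
    c_thr = float(cT[0])

    diag = np.zeros(n)
    lower = np.zeros(n - 1)  # A[i+1, i]
    upper = np.zeros(n - 1)  # A[i, i+1]
    diag[:-1] -= cL / dx
    upper[:] = -cR / dx
    lower[:] = cL / dx
    diag[1:] += cR / dx
    diag[-1] -= c_thr / dx
    return diag, lower, upper, c_thr


def stationary_density(
    config: SynapticConfig,
    model: NeuronModel,
    nu_feedback: float,
    nu_ext: Optional[float] = None,
    grid_points: int = 512,
    v_min: Optional[float] = None,
    sigma_ext_floor: float = SIGMA_EXT_FLOOR,
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Stationary density of the full operator (with reinjection) at a given
    feedback rate; returns (grid, rho, nu_Hz)."""
    mu_tot, s2 = _coefficients(config, model, nu_feedback,
                               nu_ext if nu_ext is not None else config.nu_ext,
                               sigma_ext_floor)
    sigma = np.sqrt(s2)
    v_lo = v_min if v_min is not None else model.lower_barrier(sigma)
    n = grid_points
    dx = (model.v_thr - v_lo) / n
    grid = v_lo + dx * (np.arange(n) + 0.5)
    i_res = int(np.clip((model.v_res - v_lo) / dx, 0, n - 1))
    A, c_thr = _assemble_operator(grid, dx, mu_tot, s2 / (2 * model.tau_m),
                                  model, i_res, reinject=True)
    # nullspace via bordered solve: replace last equation by normalization
    M = A.copy()
    M[-1, :] = dx
    b = np.zeros(n)
    b[-1] = 1.0
    rho = np.linalg.solve(M, b)
    nu_ms = c_thr * rho[-1]
    # account for refractory mass: total prob 1 = grid + nu*tau_ref
    if model.tau_ref > 0:
        scale = 1.0 / (1.0 + nu_ms * model.tau_ref)
        rho *= scale
        nu_ms *= scale
    return grid, rho, 1000.0 * nu_ms


def _coefficients(
    config: SynapticConfig,
    model: NeuronModel,
    nu_fb: float,
    nu_ext: float,
    sigma_ext_floor: float,
) -> Tuple[float, float]:
    """(total drift mu in mV, total variance sigma^2 in mV^2) at feedback
    rate nu_fb (Hz) and external per-source rate nu_ext (Hz)."""
    mu_I, s_I2 = recurrent_moments(nu_fb, config, model)
    rate_ms = config.C_ext * nu_ext * 1e-3
    mu_ext = model.tau_m * config.J_ext * rate_ms
    s2_ext = model.tau_m * config.J_ext**2 * rate_ms
    mu = mu_I + mu_ext + model.R * config.I_DC
    s2 = s_I2 + s2_ext + config.sigma_ext**2
    if s2 <= 0:
        s2 = sigma_ext_floor**2
    return mu, s2


@dataclass
class DensityTrajectory:
    t: np.ndarray  # ms
    nu: np.ndarray  # instantaneous flux rate (Hz)
    nu_tilde: np.ndarray  # filtered feedback rate (Hz)
    grid: np.ndarray
    snapshots: dict = field(default_factory=dict)  # t -> rho_x
    mass_error: float = 0.0  # max |1 - total probability|


def integrate_density(
    config: SynapticConfig,
    model: NeuronModel,
    T: float,
    dt: float = 0.01,
    grid_points: int = 512,
    drive: Optional[Callable[[float], float]] = None,
    tau: Optional[float] = None,
    nu_init: Optional[float] = None,
    snapshot_times: Tuple[float, ...] = (),
    v_min: Optional[float] = None,
    sigma_ext_floor: float = SIGMA_EXT_FLOOR,
) -> DensityTrajectory:
    """Integrate the 1-D FP equation with filtered feedback over T ms.

    ``drive(t)`` returns the external per-source rate nu_ext (Hz); ``tau``
    is the feedback relaxation constant tau_d (defaults to config.tau_s or
    the delay-kernel tau_d; 0 means instantaneous feedback). Starts from the
    stationary density at ``nu_init`` (defaults to the self-consistent
    stationary rate found by fixed-point iteration of the density problem).
    """
    if tau is None:
        tau = config.tau_s
        if tau == 0.0 and config.delay_kernel is not None:
            tau = config.delay_kernel.tau_d
    drive = drive or (lambda t: config.nu_ext)

    # grid sized for the largest sigma along nominal operating range
    nu_probe = nu_init if nu_init is not None else 50.0
    _, s2_probe = _coefficients(config, model, nu_probe, drive(0.0), sigma_ext_floor)
    sigma_probe = np.sqrt(s2_probe)
    v_lo = v_min if v_min is not None else model.lower_barrier(sigma_probe)
    n = grid_points
    dx = (model.v_thr - v_lo) / n
    grid = v_lo + dx * (np.arange(n) + 0.5)
    i_res = int(np.clip((model.v_res - v_lo) / dx, 0, n - 1))

    # initial condition
    if nu_init is None:
        nu_init = 10.0
        for _ in range(60):  # fixed-point iteration of the stationary problem
            _, _, nu_new = stationary_density(
                config, model, nu_init, drive(0.0), grid_points, v_lo,
                sigma_ext_floor)
            if abs(nu_new - nu_init) < 1e-6:
                nu_init = nu_new
                break
            nu_init = 0.5 * nu_init + 0.5 * nu_new
    _, rho, nu0 = stationary_density(
        config, model, nu_init, drive(0.0), grid_points, v_lo, sigma_ext_floor)
    p = rho * dx  # cell masses

    steps = int(round(T / dt))
    ref_steps = max(int(round(model.tau_ref / dt)), 0)
    dmin_steps = max(int(round(config.delta_min / dt)), 0)
    transit = deque([0.0] * ref_steps) if ref_steps else None
    in_transit = 0.0
    # initialize refractory transit at equilibrium occupancy
    if ref_steps:
        eq_flux = nu0 * 1e-3 * dt
        transit = deque([eq_flux] * ref_steps)
        in_transit = eq_flux * ref_steps
        p = p * (1.0 - in_transit) / p.sum()
    nu_hist = deque([nu0] * (dmin_steps + 1))

    nu = nu_tilde = nu0
    t_arr = np.arange(steps) * dt
    nu_out = np.empty(steps)
    nut_out = np.empty(steps)
    snapshots = {}
    snap_idx = {int(round(ts / dt)): ts for ts in snapshot_times}
    mass_err = 0.0

    for k in range(steps):
        t = t_arr[k]
        mu_tot, s2 = _coefficients(config, model, nu_tilde, drive(t), sigma_ext_floor)
        diag, lower, upper, c_thr = _banded_operator(grid, dx, mu_tot,
                                                     s2 / (2 * model.tau_m), model)
        # implicit Euler: (I - dt A) p_new = p  (A acts on densities; with
        # uniform dx the same tridiagonal acts on cell masses)
        ab = np.zeros((3, n))
        ab[0, 1:] = -dt * upper
        ab[1, :] = 1.0 - dt * diag
        ab[2, :-1] = -dt * lower
        p_new = solve_banded((1, 1), ab, p)
        absorbed = p.sum() - p_new.sum()  # mass through threshold this step
        if absorbed < 0:
            absorbed = 0.0
        # reinjection after refractory transit
        if ref_steps:
            transit.append(absorbed)
            back = transit.popleft()
            in_transit += absorbed - back
        else:
            back = absorbed
        p_new[i_res] += back
        neg = p_new < 0
        if neg.any():
            worst = p_new[neg].min()
            if worst < -1e-8:
                raise RuntimeError(
                    f"negative density {worst:.3g} beyond tolerance; reduce dt"
                )
            p_new[neg] = 0.0
        p = p_new
        nu = absorbed / dt * 1000.0  # Hz
        nu_hist.append(nu)
        nu_del = nu_hist.popleft()
        if tau > 0:
            nu_tilde += dt * (nu_del - nu_tilde) / tau
        else:
            nu_tilde = nu_del
        nu_out[k] = nu
        nut_out[k] = nu_tilde
        total = p.sum() + in_transit
        mass_err = max(mass_err, abs(1.0 - total))
        if k in snap_idx:
            snapshots[snap_idx[k]] = p / dx
    return DensityTrajectory(
        t=t_arr, nu=nu_out, nu_tilde=nut_out, grid=grid, snapshots=snapshots,
        mass_error=mass_err,
    )
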