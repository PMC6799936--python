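"""Spectral decomposition of the one-dimensional Fokker-Planck operator and
the reduced firing-rate dynamics built on it.

The membrane-potential density of an IF population driven by a filtered
synaptic current with instantaneous mean ``mu_y`` obeys, to 0-th order in the
current fluctuations, a 1-D FP equation with drift (mu_y + mu_ext - f(x))/tau_m
and diffusion (sigma_ext^2 + J*mu_y)/(2 tau_m) (the slice-dependent diffusion
sigma^2(y) = J y evaluated at y = mu_y), absorbing boundary at v_thr,
reinjection of the absorbed flux at v_res and a reflecting barrier at v_min.
Projecting the density on the biorthogonal eigenbasis {phi_n, psi_n} of this
operator produces the reduced rate equations

    da_n/dt = (lambda_n + [W0 dmu_y/dt]_{nm}) a_m + w0_n dmu_y/dt + psi0_n eta_N
    tau_s dmu_y/dt = mu_I(nu_N) - mu_y
    nu = Phi0(mu_y) + Re(f0 . a)

and, linearized around a fixed point nu*, the finite-size power spectrum

    P(w) = [1 + 2 Re(f0 . (iwI - L)^-1 psi0)]
           / |1 - (Phi0' + iw f0 . (iwI - L)^-1 w0 dmu_I/dnu) r(iw)|^2 * nu*/N

with r(iw) the Fourier transform of the spike-transmission kernel. A
first-order synaptic filter tau_s and an exponential delay kernel
tau_d = tau_s give identical r and hence identical spectra.

The operator is discretized by a Chang-Cooper finite-volume scheme
(exponentially fitted fluxes: exact for locally constant coefficients),
which conserves mass exactly, so lambda_0 = 0 to machine precision and the
stationary left eigenfunction is the constant 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import eig
from scipy.optimize import linear_sum_assignment

from .delays import DelayKernel
from .meanfield import SynapticConfig, external_moments, gain_slope
from .models import VIF, InputMoments, NeuronModel
from .spectrum import Spectrum

__all__ = [
    "SpectralBasis",
    "build_basis",
    "delay_transfer",
    "theoretical_psd",
    "BasisLattice",
    "integrate_rate_equation",
    "RateTrajectory",
]

#: default sigma_ext (mV) substituted when the configuration supplies 0, to
#: keep the absorbing boundary well-posed; override with sigma_ext_floor=0.
SIGMA_EXT_FLOOR = 1e-2


def _chang_cooper_delta(w: np.ndarray) -> np.ndarray:
    """CC weighting delta(w) = 1/w - 1/(e^w - 1), w the cell Peclet number."""
    w = np.asarray(w, dtype=float)
    out = np.empty_like(w)
    small = np.abs(w) < 1e-8
    out[small] = 0.5 - w[small] / 12.0
    ws = w[~small]
    out[~small] = 1.0 / ws - 1.0 / np.expm1(ws)
    return out


def _face_flux_coeffs(v: np.ndarray, D: float, h: float) -> Tuple[np.ndarray, np.ndarray]:
    """Coefficients (cL, cR) with F = cL*rho_left + cR*rho_right for faces with
    velocity v, diffusion D and center distance h."""
    w = v * h / D
    dlt = _chang_cooper_delta(w)
    cL = v * (1.0 - dlt) + D / h
    cR = v * dlt - D / h
    return cL, cR


def _assemble_operator(
    grid: np.ndarray,
    dx: float,
    mu_tot: float,
    D: float,
    model: NeuronModel,
    i_res: int,
    reinject: bool = True,
) -> Tuple[np.ndarray, float]:
    """Dense FP matrix A (1/ms) acting on cell densities, and the threshold
    flux coefficient c_thr with F_thr = c_thr * rho[-1]."""
    n = grid.size
    faces = grid[:-1] + dx / 2.0
    v_face = (mu_tot - model.f(faces)) / model.tau_m
    cL, cR = _face_flux_coeffs(v_face, D, dx)

    # absorbing top face at v_thr, half-cell distance, ghost density 0
    v_thr_face = (mu_tot - model.f(np.array([model.v_thr]))[0]) / model.tau_m
    cT, _ = _face_flux_coeffs(np.array([v_thr_face]), D, dx / 2.0)
    c_thr = float(cT[0])

    A = np.zeros((n, n))
    # d rho_i/dt = -(F_{i+1/2} - F_{i-1/2})/dx ; bottom face flux = 0
    for j in range(n - 1):  # interior face j between cells j and j+1
        A[j, j] -= cL[j] / dx
        A[j, j + 1] -= cR[j] / dx
        A[j + 1, j] += cL[j] / dx
        A[j + 1, j + 1] += cR[j] / dx
    A[n - 1, n - 1] -= c_thr / dx
    if reinject:
        A[i_res, n - 1] += c_thr / dx
    return A, c_thr


@dataclass
class SpectralBasis:
    """Eigenstructure of the 1-D FP operator at anchor mean current mu_y.

    Nonstationary modes are sorted by ascending |Re lambda|; the stationary
    mode (lambda = 0) is carried separately through ``Phi0`` and ``phi0``.
    All rates in Hz, eigenvalues in 1/ms, w0/W0 in 1/mV.
    """

    mu_y: float
    grid: np.ndarray
    dx: float
    Phi0: float  # stationary rate (Hz)
    lambda00: complex  # numerically ~0 stationary eigenvalue (1/ms)
    lam: np.ndarray  # nonstationary eigenvalues (1/ms)
    f0: np.ndarray  # flux couplings at v_thr (Hz, complex)
    psi0: np.ndarray  # reentry couplings psi_n(v_res)
    w0: np.ndarray  # <d_y psi_n | phi_0> (1/mV)
    W0: np.ndarray  # <d_y psi_n | phi_m>, m != 0 (1/mV)
    phi0: np.ndarray  # stationary density on the grid (1/mV)
    phi: np.ndarray = field(repr=False, default=None)  # nonstat right modes
    psi: np.ndarray = field(repr=False, default=None)  # nonstat left modes
    meta: dict = field(default_factory=dict)

    @property
    def n_modes(self) -> int:
        return self.lam.size


BASIS_CACHE_VERSION = 1


def save_basis(basis: "SpectralBasis", path) -> None:
    """Cache a spectral basis to a versioned npz container."""
    np.savez_compressed(
        path, version=BASIS_CACHE_VERSION, mu_y=basis.mu_y, grid=basis.grid,
        dx=basis.dx, Phi0=basis.Phi0, lambda00=basis.lambda00, lam=basis.lam,
        f0=basis.f0, psi0=basis.psi0, w0=basis.w0, W0=basis.W0,
        phi0=basis.phi0,
    )


def load_basis(path) -> "SpectralBasis":
    d = np.load(path)
    if int(d["version"]) != BASIS_CACHE_VERSION:
        raise ValueError(f"basis cache version {int(d['version'])} not supported")
    return SpectralBasis(
        mu_y=float(d["mu_y"]), grid=d["grid"], dx=float(d["dx"]),
        Phi0=float(d["Phi0"]), lambda00=complex(d["lambda00"]), lam=d["lam"],
        f0=d["f0"], psi0=d["psi0"], w0=d["w0"], W0=d["W0"], phi0=d["phi0"],
    )


def _eig_biortho(A: np.ndarray, dx: float, i_res: int, c_thr: float):
    """Eigendecomposition with bilinear biorthonormalization.

    Returns (lam_sorted, phi (n,k) right densities, psi (n,k) left functions,
    flux (k,) threshold fluxes in 1/ms), sorted ascending |Re lambda|. The
    left vectors satisfy psi^T A = lambda psi^T and sum(psi * phi) * dx = 1.
    """
    w, vl, vr = eig(A, left=True, right=True)
    order = np.argsort(np.abs(w.real) + 1e-12 * np.abs(w.imag))
    w = w[order]
    phi = vr[:, order]
    psi = np.conj(vl[:, order])  # bilinear left eigenvectors
    s = np.sum(psi * phi, axis=0) * dx
    bad = np.abs(s) < 1e-300
    if bad.any():
        raise RuntimeError("degenerate biorthogonal pairing in FP eigenbasis")
    psi = psi / s
    return w, phi, psi


def _match_modes(lam_ref: np.ndarray, lam_other: np.ndarray) -> np.ndarray:
    """Index array mapping each reference eigenvalue to the closest distinct
    eigenvalue of the perturbed spectrum (optimal assignment)."""
    k = lam_ref.size
    m = min(lam_other.size, max(3 * k, k + 8))
    cost = np.abs(lam_ref[:, None] - lam_other[None, :m])
    row, col = linear_sum_assignment(cost)
    out = np.empty(k, dtype=int)
    out[row] = col
    return out


def _diffusion(config: SynapticConfig, model: NeuronModel, mu_y: float,
               sigma_ext_floor: float) -> float:
    """Total diffusion coefficient (mV^2/ms) entering the operator:
    (sigma_ext_white^2 + sigma_ext_Poisson^2 + J*mu_y) / (2 tau_m)."""
    ext = external_moments(config, model)
    s2_ext = config.sigma_ext**2 + ext["sigma_ext2"]
    if s2_ext <= 0.0:
        s2_ext = sigma_ext_floor**2
    s2 = s2_ext + config.J * mu_y
    if s2 <= 0.0:
        raise ValueError(
            f"degenerate diffusion: J*mu_y + sigma_ext^2 = {s2:.3g} <= 0"
        )
    return s2 / (2.0 * model.tau_m)


def _mu_ext_offset(config: SynapticConfig, model: NeuronModel) -> float:
    ext = external_moments(config, model)
    return ext["mu_ext"] + model.R * config.I_DC


def _default_grid(model: NeuronModel, sigma: float) -> Tuple[np.ndarray, float, int]:
    v_lo = model.lower_barrier(sigma)
    n = 1024
    return v_lo, model.v_thr, n


def build_basis(
    mu_y: float,
    config: SynapticConfig,
    model: NeuronModel,
    n_modes: int = 64,
    grid_points: int = 1024,
    sigma_ext_floor: float = SIGMA_EXT_FLOOR,
    h: Optional[float] = None,
    v_min: Optional[float] = None,
    with_modes: bool = False,
) -> SpectralBasis:
    """Build the spectral basis of the FP operator anchored at ``mu_y`` (mV).

    The synaptic couplings w0/W0 are centered finite differences of the
    (gauge-aligned) adjoint eigenfunctions across mu_y +/- h."""
    D = _diffusion(config, model, mu_y, sigma_ext_floor)
    mu_off = _mu_ext_offset(config, model)
    sigma_tot = np.sqrt(2.0 * model.tau_m * D)
    v_lo = v_min if v_min is not None else model.lower_barrier(sigma_tot)
    n = grid_points
    if n_modes > n - 2:
        raise ValueError("n_modes must be <= grid_points - 2")
    dx = (model.v_thr - v_lo) / n
    grid = v_lo + dx * (np.arange(n) + 0.5)
    i_res = int(np.clip((model.v_res - v_lo) / dx, 0, n - 1))

    A, c_thr = _assemble_operator(grid, dx, mu_y + mu_off, D, model, i_res)
    w, phi, psi = _eig_biortho(A, dx, i_res, c_thr)

    lam00 = w[0]
    if abs(lam00) > 1e-6:
        raise RuntimeError(f"stationary eigenvalue not found: |lambda_0| = {abs(lam00):.3g}")
    phi0 = phi[:, 0].real
    phi0 = phi0 / (phi0.sum() * dx)
    if phi0.min() < -1e-8 * np.abs(phi0).max():
        warnings.warn("stationary density has negative undershoot beyond tolerance")
    Phi0_ms = c_thr * phi0[-1]

    k = n_modes
    lam = w[1 : k + 1]
    phi_n = phi[:, 1 : k + 1].copy()
    psi_n = psi[:, 1 : k + 1].copy()
    # fix stationary-mode normalization of the nonstationary right modes so
    # that <psi_0|phi_n> = 0 automatically (true by biorthogonality)
    flux_ms = c_thr * phi_n[-1, :]
    psi0_res = psi_n[i_res, :].copy()

    # --- couplings by centered differences across mu_y +/- h ---------------
    if h is None:
        h = 1e-3 * (model.v_thr - model.v_res)
    dpsi = np.zeros((n, k), dtype=complex)
    side_psi = []
    for s, mu_p in ((+1, mu_y + h), (-1, mu_y - h)):
        Dp = _diffusion(config, model, mu_p, sigma_ext_floor)
        Ap, c_thr_p = _assemble_operator(grid, dx, mu_p + mu_off, Dp, model, i_res)
        wp, phip, psip = _eig_biortho(Ap, dx, i_res, c_thr_p)
        idx = _match_modes(lam, wp[1:]) + 1
        psi_s = psip[:, idx]
        # gauge alignment: rescale so that <psi_n^(pm) | phi_n^(0)> = 1,
        # matching the normalization <psi_n^(0)|phi_n^(0)> = 1 of the center
        c = np.sum(psi_s * phi_n, axis=0) * dx
        psi_s = psi_s / c
        side_psi.append(psi_s)
    dpsi = (side_psi[0] - side_psi[1]) / (2.0 * h)

    w0 = np.sum(dpsi * phi0[:, None], axis=0) * dx
    W0 = (dpsi.T @ phi_n) * dx  # W0[n, m] = <d_y psi_n | phi_m>
    if config.J == 0.0:
        # no recurrence: the operator does not depend on mu_y
        w0 = np.zeros_like(w0)
        W0 = np.zeros_like(W0)

    basis = SpectralBasis(
        mu_y=mu_y,
        grid=grid,
        dx=dx,
        Phi0=1000.0 * Phi0_ms,
        lambda00=lam00,
        lam=lam,
        f0=1000.0 * flux_ms,
        psi0=psi0_res,
        w0=w0,
        W0=W0,
        phi0=phi0,
        phi=phi_n if with_modes else None,
        psi=psi_n if with_modes else None,
        meta={"D": D, "mu_ext_offset": mu_off, "c_thr": c_thr, "i_res": i_res,
              "h": h, "v_min": v_lo},
    )
    return basis


def delay_transfer(kernel: DelayKernel, omega) -> np.ndarray:
    """Exact Fourier transform r(i omega) of the kernel density
    (omega in rad/ms)."""
    return kernel.transfer(omega)


def theoretical_psd(
    freq_hz: np.ndarray,
    basis: SpectralBasis,
    nu_star: float,
    N: int,
    config: SynapticConfig,
    model: NeuronModel,
    kernel: DelayKernel = DelayKernel.none(),
    tau_s: float = 0.0,
    slope: Optional[float] = None,
) -> Spectrum:
    """Finite-size power spectrum P(omega) of nu_N around the fixed point.

    ``kernel`` carries the axonal delay distribution and ``tau_s`` an
    additional first-order synaptic filter (their transfers multiply). The
    gain slope Phi0'(nu*) is computed from the mean-field chain rule unless
    supplied."""
    freq_hz = np.asarray(freq_hz, dtype=float)
    w_ms = 2.0 * np.pi * freq_hz * 1e-3  # rad/ms
    if slope is None:
        slope = gain_slope(nu_star, config, model)
    r = np.asarray(kernel.transfer(w_ms), dtype=complex)
    if tau_s > 0.0:
        r = r * DelayKernel.exponential(tau_s).transfer(w_ms)

    lam = basis.lam[None, :]
    f_ms = basis.f0[None, :] * 1e-3  # 1/ms
    res = 1.0 / (1j * w_ms[:, None] - lam)  # diagonal resolvent (ms)
    # regularize at frequencies hitting a purely imaginary eigenvalue
    sing = np.abs(1j * w_ms[:, None] - lam) < 1e-12
    if sing.any():
        warnings.warn("resolvent regularized at eigenvalue-crossing frequency")
        res[sing] = 1.0 / 1e-12

    numer = 1.0 + 2.0 * np.real(np.sum(f_ms * res * basis.psi0[None, :], axis=1))
    dmu_dnu_ms = model.tau_m * config.J * config.C  # mV per (1/ms)
    loop = slope + 1j * w_ms * np.sum(f_ms * res * basis.w0[None, :], axis=1) * dmu_dnu_ms
    denom = np.abs(1.0 - loop * r) ** 2
    P_norm = numer / denom
    P = P_norm * nu_star / max(N, 1)
    return Spectrum(
        freq_hz=freq_hz,
        P=P,
        P_normalized=P_norm,
        meta={"N": N, "nu0": nu_star, "tau_s": tau_s, "kernel": kernel.to_dict(),
              "slope": slope, "n_modes": basis.n_modes},
    )


def theoretical_psd_exact(
    freq_hz: np.ndarray,
    config: SynapticConfig,
    model: NeuronModel,
    nu_star: float,
    N: int,
    kernel: DelayKernel = DelayKernel.none(),
    tau_s: float = 0.0,
    grid_points: int = 512,
    sigma_ext_floor: float = SIGMA_EXT_FLOOR,
    v_min: Optional[float] = None,
    h: Optional[float] = None,
) -> Spectrum:
    """Finite-size power spectrum evaluated through the full discrete
    resolvent (iw I - A)^-1 instead of a truncated eigenmode sum.

    Mathematically identical to the mode expansion summed over *all* grid
    modes: the resolvent of the discretized operator is computed directly by
    sparse linear solves, so no truncation error is introduced (the slowly
    converging mode sums of strongly drift-dominated regimes are evaluated
    exactly at the grid level). The stationary-mode component of each source
    is removed analytically."""
    freq_hz = np.asarray(freq_hz, dtype=float)
    if np.any(freq_hz <= 0):
        raise ValueError("resolvent evaluation requires strictly positive frequencies")
    from scipy.sparse import csc_matrix
    from scipy.sparse.linalg import splu

    mu_y = model.tau_m * config.J * config.C * nu_star * 1e-3
    D = _diffusion(config, model, mu_y, sigma_ext_floor)
    mu_off = _mu_ext_offset(config, model)
    sigma_tot = np.sqrt(2.0 * model.tau_m * D)
    v_lo = v_min if v_min is not None else model.lower_barrier(sigma_tot)
    n = grid_points
    dx = (model.v_thr - v_lo) / n
    grid = v_lo + dx * (np.arange(n) + 0.5)
    i_res = int(np.clip((model.v_res - v_lo) / dx, 0, n - 1))
    if h is None:
        h = 1e-3 * (model.v_thr - model.v_res)

    A, c_thr = _assemble_operator(grid, dx, mu_y + mu_off, D, model, i_res)
    # stationary density
    M = A.copy()
    M[-1, :] = dx
    b = np.zeros(n)
    b[-1] = 1.0
    phi0 = np.linalg.solve(M, b)
    # mu_y-derivative of the operator (drift and diffusion both vary)
    dA = None
    c_thr_pm = []
    for s, mu_p in ((+1, mu_y + h), (-1, mu_y - h)):
        Dp = _diffusion(config, model, mu_p, sigma_ext_floor)
        Ap, cp = _assemble_operator(grid, dx, mu_p + mu_off, Dp, model, i_res)
        dA = Ap.copy() if dA is None else dA - Ap
        c_thr_pm.append(cp)
    dA /= 2.0 * h
    dc_thr = (c_thr_pm[0] - c_thr_pm[1]) / (2.0 * h)
    src_w = dA @ phi0  # mass-conserving: no stationary component
    src_psi = np.zeros(n)
    src_psi[i_res] = 1.0 / dx

    w_ms = 2.0 * np.pi * freq_hz * 1e-3
    r = np.asarray(kernel.transfer(w_ms), dtype=complex)
    if tau_s > 0.0:
        r = r * DelayKernel.exponential(tau_s).transfer(w_ms)
    dmu_dnu_ms = model.tau_m * config.J * config.C

    numer = np.empty(freq_hz.size)
    loop = np.empty(freq_hz.size, dtype=complex)
    eye_idx = np.arange(n)
    for k, w in enumerate(w_ms):
        Mw = (-A).astype(complex)
        Mw[eye_idx, eye_idx] += 1j * w
        lu = splu(csc_matrix(Mw))
        x_psi = lu.solve(src_psi.astype(complex))
        fpsi = c_thr * (x_psi[-1] - phi0[-1] / (1j * w))  # dimensionless
        numer[k] = 1.0 + 2.0 * np.real(fpsi)
        x_w = lu.solve(src_w.astype(complex))
        dnudmu = c_thr * x_w[-1] + dc_thr * phi0[-1]  # (1/ms)/mV response
        loop[k] = dnudmu * dmu_dnu_ms
    P_norm = numer / np.abs(1.0 - loop * r) ** 2
    P = P_norm * nu_star / max(N, 1)
    return Spectrum(
        freq_hz=freq_hz, P=P, P_normalized=P_norm,
        meta={"N": N, "nu0": nu_star, "tau_s": tau_s,
              "kernel": kernel.to_dict(), "method": "resolvent",
              "grid_points": grid_points},
    )


# ---------------------------------------------------------------------------
# basis families over a mu_y lattice, for time integration
# ---------------------------------------------------------------------------


class BasisLattice:
    """Spectral bases precomputed on a mu_y lattice with a smooth gauge.

    Modes are matched across neighbouring lattice points by eigenvalue
    continuity and rescaled so that the biorthogonal gauge varies smoothly;
    eigenvalues and coupling coefficients are then linearly interpolated in
    mu_y."""

    def __init__(
        self,
        mu_y_values: Sequence[float],
        config: SynapticConfig,
        model: NeuronModel,
        n_modes: int = 16,
        grid_points: int = 512,
        sigma_ext_floor: float = SIGMA_EXT_FLOOR,
        v_min: Optional[float] = None,
    ):
        mu_y_values = np.sort(np.asarray(mu_y_values, dtype=float))
        if v_min is None:
            # common grid wide enough for the largest diffusion on the lattice
            D_max = max(
                _diffusion(config, model, m, sigma_ext_floor) for m in mu_y_values
            )
            v_min = model.lower_barrier(np.sqrt(2 * model.tau_m * D_max))
        bases = [
            build_basis(
                m, config, model, n_modes=n_modes, grid_points=grid_points,
                sigma_ext_floor=sigma_ext_floor, v_min=v_min, with_modes=True,
            )
            for m in mu_y_values
        ]
        # align mode ordering and gauge along the lattice
        for k in range(1, len(bases)):
            prev, cur = bases[k - 1], bases[k]
            idx = _match_modes(prev.lam, cur.lam)
            cur.lam = cur.lam[idx]
            cur.f0 = cur.f0[idx]
            cur.psi0 = cur.psi0[idx]
            cur.w0 = cur.w0[idx]
            cur.W0 = cur.W0[np.ix_(idx, idx)]
            cur.phi = cur.phi[:, idx]
            cur.psi = cur.psi[:, idx]
            c = np.sum(cur.psi * prev.phi, axis=0) * cur.dx
            c = np.where(np.abs(c) > 1e-12, c, 1.0)
            cur.psi = cur.psi / c
            cur.phi = cur.phi * c
            cur.f0 = cur.f0 * c
            cur.psi0 = cur.psi0 / c
            cur.w0 = cur.w0 / c
            cur.W0 = cur.W0 * (c[None, :] / c[:, None])
        self.mu_y = mu_y_values
        self.bases = bases
        self.Phi0 = np.array([b.Phi0 for b in bases])
        self.lam = np.array([b.lam for b in bases])
        self.f0 = np.array([b.f0 for b in bases])
        self.psi0 = np.array([b.psi0 for b in bases])
        self.w0 = np.array([b.w0 for b in bases])
        self.W0 = np.array([b.W0 for b in bases])
        self.n_modes = n_modes

    def at(self, mu_y: float):
        """Interpolated (Phi0, lam, f0, psi0, w0, W0) at mu_y (clamped to the
        lattice range)."""
        x = self.mu_y
        m = float(np.clip(mu_y, x[0], x[-1]))
        j = int(np.clip(np.searchsorted(x, m) - 1, 0, x.size - 2))
        t = (m - x[j]) / (x[j + 1] - x[j])
        interp = lambda a: a[j] * (1 - t) + a[j + 1] * t
        return (
            interp(self.Phi0),
            interp(self.lam),
            interp(self.f0),
            interp(self.psi0),
            interp(self.w0),
            interp(self.W0),
        )


@dataclass
class RateTrajectory:
    t: np.ndarray  # ms
    nu: np.ndarray  # Hz (infinite-size component)
    nu_N: np.ndarray  # Hz (finite-size rate)
    mu_y: np.ndarray  # mV
    clipped_steps: int = 0


def integrate_rate_equation(
    provider: BasisLattice,
    config: SynapticConfig,
    model: NeuronModel,
    T: float,
    dt: float = 0.05,
    N: Optional[int] = None,
    tau: Optional[float] = None,
    seed: int = 0,
    drive: Optional[Callable[[float], float]] = None,
    nu0: Optional[float] = None,
) -> RateTrajectory:
    """Explicit first-order integration of the reduced firing-rate equations.

    ``tau`` is the relaxation time of the filtered mean current (the synaptic
    time constant, or the decay constant of an equivalent exponential delay
    kernel); defaults to config.tau_s or the kernel tau_d. ``N = None``
    integrates the infinite-size limit (no finite-size noise). ``drive`` maps
    t (ms) to the external per-source rate nu_ext (Hz); changes in the
    external mean current are folded into the mu_y coordinate of the basis
    lattice (external input is instantaneous, so its mean shifts the operator
    exactly like the filtered recurrent mean)."""
    if tau is None:
        tau = config.tau_s
        if tau == 0.0 and config.delay_kernel is not None:
            tau = config.delay_kernel.tau_d
    tau = max(tau, 1e-3)
    lam_max = np.max(np.abs(provider.lam.real))
    if lam_max * dt > 0.5:
        raise ValueError(
            f"dt = {dt} ms unstable for fastest retained mode "
            f"(|Re lambda|max = {lam_max:.3g}/ms); use dt < {0.5 / lam_max:.3g} ms"
        )
    rng = np.random.default_rng(seed)
    steps = int(round(T / dt))
    nsk = provider.n_modes

    mu_ext0 = _mu_ext_offset(config, model)

    def mu_ext_of(t: float) -> float:
        if drive is None:
            return mu_ext0
        c2 = SynapticConfig(
            N=config.N, C=config.C, J=config.J, J_ext=config.J_ext,
            C_ext=config.C_ext, nu_ext=drive(t), I_DC=config.I_DC,
            sigma_ext=config.sigma_ext,
        )
        return _mu_ext_offset(c2, model)

    mu_I_of = lambda nu_hz: model.tau_m * config.J * config.C * nu_hz * 1e-3

    # initial condition: stationary at nu0 (self-consistent anchor)
    if nu0 is None:
        nu0 = provider.Phi0[len(provider.Phi0) // 2]
    mu_y = mu_I_of(nu0)
    a = np.zeros(nsk, dtype=complex)

    dbuf_len = max(int(round(config.delta_min / dt)), 0)
    dbuf = [nu0] * (dbuf_len + 1)

    t_arr = np.arange(steps) * dt
    nu_out = np.empty(steps)
    nuN_out = np.empty(steps)
    muy_out = np.empty(steps)
    clipped = 0
    mu_ext_prev = mu_ext_of(0.0)
    nu = nu_N = nu0
    for i in range(steps):
        t = t_arr[i]
        nu_fb = dbuf[0] if dbuf_len else nu_N
        mu_I = mu_I_of(nu_fb)
        # actual per-step change of mu_y under the exact relaxation update:
        # the coupling terms integrate mu_y-dot over the step
        dmu_y = (mu_I - mu_y) * (-np.expm1(-dt / tau)) / dt
        mu_ext_t = mu_ext_of(t + dt)
        dmu_ext = (mu_ext_t - mu_ext_prev) / dt
        mu_ext_prev = mu_ext_t
        Phi0, lam, f0, psi0, w0, W0 = provider.at(mu_y + (mu_ext_t - mu_ext0))
        mdot = dmu_y + dmu_ext
        if N is not None:
            eta_ms = rng.normal(0.0, np.sqrt(max(nu, 0.0) * 1e-3 / (N * dt)))
        else:
            eta_ms = 0.0
        # exponential integrator in the stiff diagonal part; mu_y relaxation
        # integrated exactly (stable down to the instantaneous-feedback limit)
        a = np.exp(lam * dt) * a + dt * (mdot * (W0 @ a) + w0 * mdot + psi0 * eta_ms)
        mu_y = mu_y + dmu_y * dt
        nu = Phi0 + np.real(np.dot(f0, a))
        if nu < 0.0:
            nu = 0.0
            clipped += 1
        nu_N = nu + eta_ms * 1e3
        if dbuf_len:
            dbuf.append(nu_N)
            dbuf.pop(0)
        nu_out[i] = nu
        nuN_out[i] = nu_N
        muy_out[i] = mu_y
    return RateTrajectory(t=t_arr, nu=nu_out, nu_N=nuN_out, mu_y=muy_out,
                          clipped_steps=clipped)
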