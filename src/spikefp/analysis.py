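"""Spectral estimation, filter/delay equivalence metrics, bifurcation sweeps
and marginal densities from simulation output.

Power spectra use Welch averaging (Hann window, 50% overlap) on the binned
population rate after discarding the initial transient, converted to the
two-sided-density convention in which N independent Poisson neurons at rate
nu0 give a flat floor nu0/N; normalized spectra P*N/nu0 therefore approach 1
at high frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import welch

from .netsim import NetworkSpec, SimOutput, simulate
from .spectrum import Spectrum

__all__ = [
    "estimate_psd",
    "psd_from_runs",
    "equivalence_zscore",
    "EquivalenceSummary",
    "sweep_bifurcation",
    "marginals",
]


def _single_psd(x: np.ndarray, fs_hz: float, segment_s: float):
    nper = int(round(segment_s * fs_hz))
    nper = min(nper, x.size)
    f, p = welch(x, fs=fs_hz, window="hann", nperseg=nper,
                 noverlap=nper // 2, detrend="constant")
    # welch is one-sided (doubled); convert to the two-sided convention
    return f, p / 2.0


def estimate_psd(
    nu_series: Sequence[np.ndarray],
    dt_ms: float,
    N: int,
    discard_ms: float = 1000.0,
    segment_ms: float = 2000.0,
) -> Spectrum:
    """Welch spectrum of the population rate, averaged over realizations.

    ``nu_series`` is a list of rate time series (Hz, one per realization)
    sampled every ``dt_ms``; the first ``discard_ms`` of each is dropped.
    Returns mean and SEM across realizations of the normalized spectrum."""
    fs = 1000.0 / dt_ms
    n_discard = int(round(discard_ms / dt_ms))
    ps, nu0s = [], []
    f = None
    for x in nu_series:
        x = np.asarray(x, dtype=float)[n_discard:]
        if x.size * dt_ms < 2 * segment_ms:
            raise ValueError("series shorter than discard + 2 segments")
        f, p = _single_psd(x, fs, segment_ms / 1000.0)
        ps.append(p)
        nu0s.append(x.mean())
    ps = np.asarray(ps)
    nu0 = float(np.mean(nu0s))
    norm = N / nu0
    Pn = ps * norm
    mean = Pn.mean(axis=0)
    sem = (Pn.std(axis=0, ddof=1) / np.sqrt(len(ps))) if len(ps) > 1 else np.zeros_like(mean)
    m = f > 0
    return Spectrum(
        freq_hz=f[m], P=mean[m] / norm, P_normalized=mean[m], sem=sem[m],
        meta={"N": N, "nu0": nu0, "n_realizations": len(ps),
              "per_realization": Pn[:, m]},
    )


def psd_from_runs(
    spec_builder: Callable[[int], NetworkSpec],
    T: float,
    n_realizations: int,
    pop: int = 0,
    discard_ms: float = 1000.0,
    segment_ms: float = 2000.0,
) -> Spectrum:
    """Simulate ``n_realizations`` networks (seed = realization index passed
    to the builder) and estimate the population-rate spectrum."""
    series = []
    N = None
    dt_bin = None
    for k in range(n_realizations):
        out = simulate(spec_builder(k), T)
        series.append(out.nu[:, pop])
        N = out.meta["N"][pop]
        dt_bin = float(out.t_bins[1] - out.t_bins[0])
    return estimate_psd(series, dt_bin, N, discard_ms, segment_ms)


@dataclass
class EquivalenceSummary:
    freq_hz: np.ndarray
    delta_P: np.ndarray  # P_d/P_s - 1 (mean over realizations)
    z: np.ndarray  # per-frequency z-score of the difference
    median_abs_z: float
    frac_abs_z_below_3: float

    def cdf(self):
        zs = np.sort(np.abs(self.z))
        return zs, np.arange(1, zs.size + 1) / zs.size


def equivalence_zscore(spectrum_delays: Spectrum, spectrum_filter: Spectrum,
                       f_lo: float = 1.0, f_hi: float = 200.0) -> EquivalenceSummary:
    """Per-frequency relative spectral difference DeltaP = P_d/P_s - 1
    between the delay-distribution and synaptic-filter protocols, expressed
    as z-scores (difference of realization means over the pooled SEM)."""
    fd, ff = spectrum_delays.freq_hz, spectrum_filter.freq_hz
    Pd = spectrum_delays.meta["per_realization"]
    Ps = spectrum_filter.meta["per_realization"]
    if fd.size != ff.size or not np.allclose(fd, ff):
        import warnings

        warnings.warn("frequency grids differ; resampling filter spectrum")
        Ps = np.array([np.interp(fd, ff, row) for row in Ps])
        ff = fd
    m = (fd >= f_lo) & (fd <= f_hi)
    f = fd[m]
    Pd, Ps = Pd[:, m], Ps[:, m]
    nd, ns = Pd.shape[0], Ps.shape[0]
    md, ms = Pd.mean(axis=0), Ps.mean(axis=0)
    vd = Pd.var(axis=0, ddof=1) / nd if nd > 1 else np.zeros_like(md)
    vs = Ps.var(axis=0, ddof=1) / ns if ns > 1 else np.zeros_like(ms)
    pooled = np.sqrt(vd + vs)
    pooled[pooled == 0] = np.inf
    z = (md - ms) / pooled
    dP = md / ms - 1.0
    return EquivalenceSummary(
        freq_hz=f, delta_P=dP, z=z,
        median_abs_z=float(np.median(np.abs(z))),
        frac_abs_z_below_3=float(np.mean(np.abs(z) < 3.0)),
    )


def classify_state(nu0: float, spectrum: Spectrum, nu_target: float,
                   low_thresh: float = 0.8, peak_factor: float = 10.0,
                   f_max: float = 200.0) -> str:
    """AL / AH / GO decision rule: AL if the mean rate is below
    low_thresh * nu_target; GO if the tallest spectral peak below f_max
    exceeds peak_factor times the high-frequency floor; else AH."""
    if nu0 < low_thresh * nu_target:
        return "AL"
    band = spectrum.band(1.0, f_max)
    floor = float(np.median(spectrum.P_normalized[spectrum.freq_hz > 0.7 * spectrum.freq_hz.max()]))
    if band.P_normalized.max() > peak_factor * max(floor, 1e-12):
        return "GO"
    return "AH"


def sweep_bifurcation(
    builder: Callable[[float, int], NetworkSpec],
    c_values: Sequence[float],
    T: float,
    n_realizations: int = 1,
    seeds: Optional[Sequence[int]] = None,
    nu_target: float = 10.0,
    discard_ms: float = 1000.0,
    segment_ms: float = 1000.0,
    classifier_kwargs: Optional[dict] = None,
    classify_pop: int = -1,
) -> pd.DataFrame:
    """Sweep a bifurcation parameter; ``builder(c, seed)`` yields a network.

    Returns one row per c with per-population mean rate nu0, std sigma_nu,
    c_v = sigma_nu/nu0 (from 0.1-ms binned rates, first second discarded)
    and the AL/AH/GO state label of the population selected by
    ``classify_pop``."""
    seeds = list(seeds) if seeds is not None else list(range(n_realizations))
    rows = []
    for c in c_values:
        stats = None
        series_per_pop: List[List[np.ndarray]] = []
        labels = None
        Ns = None
        dt_bin = None
        for s in seeds:
            out = simulate(builder(c, s), T)
            m = out.t_bins >= discard_ms
            if stats is None:
                n_pops = out.nu.shape[1]
                stats = [[] for _ in range(n_pops)]
                series_per_pop = [[] for _ in range(n_pops)]
                labels = out.labels
                Ns = out.meta["N"]
                dt_bin = float(out.t_bins[1] - out.t_bins[0])
            for ip in range(out.nu.shape[1]):
                x = out.nu[m, ip]
                stats[ip].append((x.mean(), x.std()))
                series_per_pop[ip].append(out.nu[:, ip])
        row = {"c": c}
        for ip, lab in enumerate(labels):
            mu = float(np.mean([a for a, _ in stats[ip]]))
            sd = float(np.mean([b for _, b in stats[ip]]))
            row[f"nu0_{lab}"] = mu
            row[f"sigma_nu_{lab}"] = sd
            row[f"c_v_{lab}"] = sd / mu if mu > 0 else np.inf
        sp = estimate_psd(series_per_pop[classify_pop], dt_bin, Ns[classify_pop],
                          discard_ms, segment_ms)
        row["state"] = classify_state(row[f"nu0_{labels[classify_pop]}"], sp,
                                      nu_target, **(classifier_kwargs or {}))
        rows.append(row)
    return pd.DataFrame(rows)


def marginals(
    sim: SimOutput,
    model_R: float,
    mu_I: float,
    discard_ms: float = 1000.0,
    bins: int = 80,
    slice_bandwidth: Optional[float] = None,
) -> dict:
    """Marginal densities rho(V), rho(I) (I in voltage units u = R*I) and the
    conditional slice rho(V | u ~ mu_I) from tagged-neuron trajectories.

    Densities are normalized to unit area; the slice is estimated from
    samples with |u - mu_I| < bandwidth (widened automatically if too few
    samples fall inside)."""
    if sim.tagged_V is None:
        raise ValueError("simulation was run without tagged neurons")
    m = sim.tagged_t >= discard_ms
    V = sim.tagged_V[m].ravel()
    u = sim.tagged_u[m].ravel()
    rho_V, eV = np.histogram(V, bins=bins, density=True)
    rho_u, eu = np.histogram(u, bins=bins, density=True)
    bw = slice_bandwidth if slice_bandwidth is not None else 0.1 * max(u.std(), 1e-12)
    for _ in range(10):
        sel = np.abs(u - mu_I) < bw
        if sel.sum() >= 200 or bw > 10 * max(u.std(), 1e-12):
            break
        bw *= 2.0
    else:
        import warnings

        warnings.warn("slice bandwidth widened to capture enough samples")
    rho_slice, es = np.histogram(V[sel], bins=bins, density=True)
    centers = lambda e: 0.5 * (e[1:] + e[:-1])
    return {
        "V": (centers(eV), rho_V),
        "I": (centers(eu), rho_u),
        "slice": (centers(es), rho_slice),
        "n_slice_samples": int(sel.sum()),
        "bandwidth": bw,
    }
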