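"""Integrate-and-fire neuron model descriptions.

Three model flavours are supported:

``VIF``
    "VLSI" integrate-and-fire: a perfect integrator with constant leak
    (absorbed into the bias current), a reflecting barrier at ``V = 0`` and
    threshold at ``V = 1``. Voltages are expressed in units of the firing
    threshold and time in ms; by convention ``tau_m = 1`` and ``C_m = 1`` so
    that drifts are stated in v_thr/ms and diffusions in v_thr^2/ms.
``LIF``
    Leaky integrate-and-fire, linear leak ``f(V) = V - E_L``.
``EIF``
    Exponential integrate-and-fire with spike-initiation term
    ``f(V) = (V - E_L) - Delta_T * exp((V - v_thr)/Delta_T)`` and a numerical
    spike cutoff at ``V_peak``.

All quantities are in (mV, ms, Hz, pA, pF) unless the model is VIF, in which
case the voltage unit is the threshold itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

VIF = "VIF"
LIF = "LIF"
EIF = "EIF"
_KINDS = (VIF, LIF, EIF)


@dataclass(frozen=True)
class NeuronModel:
    """Static single-cell description defining the leakage drift f(V)."""

    kind: str
    tau_m: float  # membrane time constant (ms)
    C_m: float  # membrane capacitance (pF)
    v_thr: float  # spike threshold (mV; 1 for VIF)
    v_res: float  # reset potential
    v_min: Optional[float] = None  # reflecting lower barrier (None -> auto)
    tau_ref: float = 0.0  # absolute refractory period (ms)
    E_L: float = 0.0  # leak/resting potential (LIF/EIF)
    Delta_T: Optional[float] = None  # spike slope factor (EIF)
    V_peak: Optional[float] = None  # numerical spike cutoff (EIF)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown neuron kind {self.kind!r}; expected one of {_KINDS}")
        if self.tau_m <= 0 or self.C_m <= 0:
            raise ValueError("tau_m and C_m must be positive")
        if self.tau_ref < 0:
            raise ValueError("tau_ref must be nonnegative")
        if not self.v_res < self.v_thr:
            raise ValueError("v_res must lie below v_thr")
        if self.v_min is not None and self.v_min > self.v_res:
            raise ValueError("v_min must not exceed v_res")
        if self.kind == EIF:
            if self.Delta_T is None or self.Delta_T <= 0:
                raise ValueError("EIF requires Delta_T > 0")
            if self.V_peak is None or self.V_peak <= self.v_thr:
                raise ValueError("EIF requires V_peak > v_thr")
        if self.kind == VIF:
            if self.v_min not in (None, 0.0) or self.v_res != 0.0:
                raise ValueError("VIF convention: v_min = v_res = 0")

    @property
    def R(self) -> float:
        """Membrane resistance tau_m / C_m (GOhm when pF/ms, 1 for VIF)."""
        return self.tau_m / self.C_m

    @property
    def g_L(self) -> float:
        """Leak conductance C_m / tau_m (nS)."""
        return self.C_m / self.tau_m

    def f(self, v: np.ndarray) -> np.ndarray:
        """Voltage-dependent leakage drift f(V) (mV), entering
        tau_m dV/dt = -f(V) + mu + noise."""
        v = np.asarray(v, dtype=float)
        if self.kind == VIF:
            return np.zeros_like(v)
        if self.kind == LIF:
            return v - self.E_L
        # EIF
        return (v - self.E_L) - self.Delta_T * np.exp((v - self.v_thr) / self.Delta_T)

    def lower_barrier(self, sigma: float, mu: float = 0.0) -> float:
        """Effective reflecting barrier. VIF has a hard barrier at 0;
        LIF/EIF default to 10 sigma below min(v_res, E_L + min(mu, 0))."""
        if self.kind == VIF:
            return 0.0
        if self.v_min is not None:
            return self.v_min
        base = min(self.v_res, self.E_L + min(mu, 0.0))
        return base - 10.0 * max(sigma, 0.5)

    def spike_cutoff(self) -> float:
        """Voltage at which a spike is registered (v_thr, or V_peak for EIF)."""
        return self.V_peak if self.kind == EIF else self.v_thr

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NeuronModel":
        return cls(**d)


def vif_neuron(tau_ref: float = 0.0) -> NeuronModel:
    """VIF neuron in threshold units (tau_m = 1 ms, C_m = 1)."""
    return NeuronModel(kind=VIF, tau_m=1.0, C_m=1.0, v_thr=1.0, v_res=0.0,
                       v_min=0.0, tau_ref=tau_ref, E_L=0.0)


def lif_neuron(tau_m: float = 20.0, C_m: float = 500.0, v_thr: float = 20.0,
               v_res: float = 0.0, E_L: float = 0.0, tau_ref: float = 0.0,
               v_min: Optional[float] = None) -> NeuronModel:
    return NeuronModel(kind=LIF, tau_m=tau_m, C_m=C_m, v_thr=v_thr,
                       v_res=v_res, v_min=v_min, tau_ref=tau_ref, E_L=E_L)


def eif_neuron(tau_m: float = 10.0, C_m: float = 500.0, v_thr: float = -59.9,
               v_res: float = -68.0, E_L: float = -65.0, Delta_T: float = 3.48,
               V_peak: float = 0.0, tau_ref: float = 1.7,
               v_min: Optional[float] = None) -> NeuronModel:
    return NeuronModel(kind=EIF, tau_m=tau_m, C_m=C_m, v_thr=v_thr,
                       v_res=v_res, v_min=v_min, tau_ref=tau_ref, E_L=E_L,
                       Delta_T=Delta_T, V_peak=V_peak)


@dataclass(frozen=True)
class InputMoments:
    """First two infinitesimal moments of the effective white-noise drive.

    ``mu`` is the total mean input (mV; for VIF: v_thr/ms) and ``sigma2`` the
    total input variance (mV^2; for VIF: v_thr^2/ms).
    """

    mu: float
    sigma2: float

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be nonnegative")

    @property
    def sigma(self) -> float:
        return float(np.sqrt(self.sigma2))
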