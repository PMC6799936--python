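"""Axonal delay distributions and their exact Fourier transforms.

A spike-transmission kernel rho_d(delta) is a normalized density on
[0, inf). Its Fourier transform r(i omega) = int rho_d(d) e^{-i omega d} dd
is the loop filter entering the finite-size power spectrum; a first-order
synaptic filter with decay tau_s is equivalent to an exponential kernel with
tau_d = tau_s (identical r), a cascade of a fixed delay and a filter gives
r = exp(-i omega delta)/(1 + i omega tau), and the convolution of two
exponentials ("beta" kernel, "alpha" in the equal-tau limit) gives the
product of the two first-order transfers.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

__all__ = ["DelayKernel"]

_KINDS = ("none", "exponential", "fixed", "fixed_plus_exponential", "beta", "alpha")


@dataclass(frozen=True)
class DelayKernel:
    """Delay distribution; parameters in ms.

    kinds: none | exponential(tau_d) | fixed(delta) |
    fixed_plus_exponential(delta, tau_d) | beta(tau_d1, tau_d2) | alpha(tau_d)
    """

    kind: str = "none"
    tau_d: float = 0.0
    delta: float = 0.0
    tau_d2: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown delay kernel {self.kind!r}")
        if self.tau_d < 0 or self.delta < 0 or self.tau_d2 < 0:
            raise ValueError("delay kernel parameters must be nonnegative")

    # ------------------------------------------------------------------ #
    @classmethod
    def none(cls) -> "DelayKernel":
        return cls("none")

    @classmethod
    def exponential(cls, tau_d: float) -> "DelayKernel":
        return cls("exponential", tau_d=tau_d)

    @classmethod
    def fixed(cls, delta: float) -> "DelayKernel":
        return cls("fixed", delta=delta)

    @classmethod
    def fixed_plus_exponential(cls, delta: float, tau_d: float) -> "DelayKernel":
        return cls("fixed_plus_exponential", delta=delta, tau_d=tau_d)

    @classmethod
    def beta(cls, tau_d1: float, tau_d2: float) -> "DelayKernel":
        return cls("beta", tau_d=tau_d1, tau_d2=tau_d2)

    @classmethod
    def alpha(cls, tau_d: float) -> "DelayKernel":
        return cls("alpha", tau_d=tau_d)

    # ------------------------------------------------------------------ #
    @property
    def mean(self) -> float:
        if self.kind == "none":
            return 0.0
        if self.kind == "exponential":
            return self.tau_d
        if self.kind == "fixed":
            return self.delta
        if self.kind == "fixed_plus_exponential":
            return self.delta + self.tau_d
        if self.kind == "beta":
            return self.tau_d + self.tau_d2
        return 2.0 * self.tau_d  # alpha

    def transfer(self, omega) -> np.ndarray:
        """Exact Fourier transform r(i omega); omega in rad/ms.
        |r| <= 1 and r(0) = 1."""
        w = np.asarray(omega, dtype=float)
        iw = 1j * w
        if self.kind == "none":
            r = np.ones_like(w, dtype=complex)
        elif self.kind == "exponential":
            r = 1.0 / (1.0 + iw * self.tau_d)
        elif self.kind == "fixed":
            r = np.exp(-iw * self.delta)
        elif self.kind == "fixed_plus_exponential":
            r = np.exp(-iw * self.delta) / (1.0 + iw * self.tau_d)
        elif self.kind == "beta":
            r = 1.0 / ((1.0 + iw * self.tau_d) * (1.0 + iw * self.tau_d2))
        else:  # alpha
            r = 1.0 / (1.0 + iw * self.tau_d) ** 2
        return r if r.shape else complex(r)

    def density(self, delta) -> np.ndarray:
        """Kernel density rho_d(delta) (1/ms); the fixed part is represented
        only through sampling/transfer (a Dirac mass has no density)."""
        d = np.asarray(delta, dtype=float)
        out = np.zeros_like(d)
        if self.kind == "exponential":
            m = d >= 0
            out[m] = np.exp(-d[m] / self.tau_d) / self.tau_d
        elif self.kind == "fixed_plus_exponential":
            m = d >= self.delta
            out[m] = np.exp(-(d[m] - self.delta) / self.tau_d) / self.tau_d
        elif self.kind == "beta":
            t1, t2 = self.tau_d, self.tau_d2
            m = d >= 0
            if abs(t1 - t2) < 1e-12:
                out[m] = d[m] * np.exp(-d[m] / t1) / t1**2
            else:
                out[m] = (np.exp(-d[m] / t1) - np.exp(-d[m] / t2)) / (t1 - t2)
        elif self.kind == "alpha":
            m = d >= 0
            out[m] = d[m] * np.exp(-d[m] / self.tau_d) / self.tau_d**2
        elif self.kind in ("none", "fixed"):
            raise ValueError(f"kernel {self.kind!r} is a Dirac mass; no density")
        return out

    def sample(self, n: int, rng: np.random.Generator, low: float = 0.0) -> np.ndarray:
        """n i.i.d. delays (ms), shifted/clipped so the minimum is ``low``."""
        if self.kind == "none":
            return np.full(n, low)
        if self.kind == "fixed":
            return np.full(n, max(self.delta, low))
        if self.kind == "exponential":
            return low + rng.exponential(self.tau_d, n)
        if self.kind == "fixed_plus_exponential":
            return max(self.delta, low) + rng.exponential(self.tau_d, n)
        if self.kind == "beta":
            return low + rng.exponential(self.tau_d, n) + rng.exponential(self.tau_d2, n)
        # alpha
        return low + rng.gamma(2.0, self.tau_d, n)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DelayKernel":
        return cls(**d)
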