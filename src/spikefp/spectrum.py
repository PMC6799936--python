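"""Shared container for power spectra of the population firing rate."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd


@dataclass
class Spectrum:
    """Power spectral density of the population rate nu_N(t).

    ``P`` is the two-sided-convention density (flat shot-noise floor
    nu0/N Hz), ``P_normalized`` = P * N / nu0 (floor 1), ``sem`` the
    per-frequency standard error across realizations (None for theoretical
    spectra)."""

    freq_hz: np.ndarray
    P: np.ndarray
    P_normalized: np.ndarray
    sem: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "omega_over_2pi_Hz": self.freq_hz,
                "P_raw": self.P,
                "P_normalized": self.P_normalized,
            }
        )
        if self.sem is not None:
            df["sem_normalized"] = self.sem
        return df

    def band(self, f_lo: float, f_hi: float) -> "Spectrum":
        m = (self.freq_hz >= f_lo) & (self.freq_hz <= f_hi)
        return Spectrum(
            self.freq_hz[m],
            self.P[m],
            self.P_normalized[m],
            None if self.sem is None else self.sem[m],
            dict(self.meta),
        )
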