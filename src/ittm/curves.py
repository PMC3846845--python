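"""Time-series containers shared across the package."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AccumulationCurve", "PlasmaDecayModel"]

#: Allowed concentration bases for an accumulation curve.
CURVE_BASES = ("total-tumor", "interstitial", "blood", "plasma")


@dataclass
class AccumulationCurve:
    """Volume-averaged iodine concentration versus time.

    Attributes
    ----------
    times : ndarray
        Sample times, hours, strictly ascending.
    conc : ndarray
        Mean iodine concentration, mgI cm^-3, non-negative.
    basis : str
        What volume the concentration refers to: ``total-tumor``,
        ``interstitial``, ``blood`` or ``plasma``.
    """

    times: np.ndarray
    conc: np.ndarray
    basis: str = "total-tumor"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.times.shape != self.conc.shape:
            raise ValueError("times and conc must have the same shape")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.basis not in CURVE_BASES:
            raise ValueError(f"basis must be one of {CURVE_BASES}, got {self.basis!r}")

    def __len__(self) -> int:
        return self.times.size

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_hr": self.times, "conc_mgI_per_cm3": self.conc}
        )


@dataclass
class PlasmaDecayModel:
    """One-compartment plasma pharmacokinetics: C_p(t) = c0 * 2^(-t/t_half).

    Attributes
    ----------
    c0 : float
        Peak plasma iodine concentration, mgI cm^-3.
    t_half : float
        Plasma half-life, hours.
    """

    c0: float
    t_half: float

    def __post_init__(self) -> None:
        if self.c0 <= 0:
            raise ValueError(f"c0 must be positive, got {self.c0}")
        if self.t_half <= 0:
            raise ValueError(f"t_half must be positive, got {self.t_half}")

    @property
    def k_elim(self) -> float:
        """Elimination rate constant, hr^-1 (ln 2 / t_half)."""
        return np.log(2.0) / self.t_half

    def __call__(self, t_hr):
        """Plasma concentration at time ``t_hr`` (hours), mgI cm^-3."""
        t = np.asarray(t_hr, dtype=float)
        out = self.c0 * np.exp2(-t / self.t_half)
        return out if out.ndim else float(out)

    def to_dict(self) -> dict:
        return {"c0_mgI_per_cm3": self.c0, "t_half_hr": self.t_half}
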