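"""Image-derived pharmacokinetics and tumor accumulation quantities.

Converts contrast-enhanced CT region means into the quantities the
transport model consumes: HU -> iodine concentration via a linear
calibration factor, aorta blood -> plasma concentration via the
hematocrit, a one-compartment plasma decay fit, the plasma volume
fraction from the first post-injection time point, vascular-compartment
subtraction, and the equivalent spherical radius of the contoured tumor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .curves import AccumulationCurve, PlasmaDecayModel

__all__ = [
    "ImagingSeries",
    "PlasmaFitResult",
    "SeriesAnalysis",
    "hu_to_iodine",
    "blood_to_plasma",
    "fit_one_compartment",
    "estimate_plasma_volume_fraction",
    "subtract_vascular_contribution",
    "equivalent_radius",
    "analyze_series",
]

logger = logging.getLogger(__name__)

#: CT calibration factors, HU per mgI cm^-3.
CALIBRATION_MOUSE = 50.1
CALIBRATION_RABBIT = 38.0

#: Default arterial hematocrit used to convert blood to plasma concentration.
DEFAULT_HEMATOCRIT = 0.40


@dataclass
class ImagingSeries:
    """Longitudinal CT region-mean series for one tumor.

    The first row is the pre-injection baseline scan; subsequent rows
    are post-injection.  Signals are either raw Hounsfield units
    (``units="HU"``, requiring a calibration factor) or already-
    converted iodine concentrations (``units="mgI"``).
    """

    times: np.ndarray          # hours; times[0] is the pre-injection scan
    tumor: np.ndarray          # HU or mgI cm^-3 (tumor region mean)
    blood: np.ndarray          # HU or mgI cm^-3 (aorta region mean)
    volume_mm3: np.ndarray | None = None
    units: str = "HU"
    calibration: float | None = None   # HU per mgI cm^-3
    hematocrit: float = DEFAULT_HEMATOCRIT
    species_label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.tumor = np.asarray(self.tumor, dtype=float)
        self.blood = np.asarray(self.blood, dtype=float)
        if self.volume_mm3 is not None:
            self.volume_mm3 = np.asarray(self.volume_mm3, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.units not in ("HU", "mgI"):
            raise ValueError(f"units must be 'HU' or 'mgI', got {self.units!r}")
        if self.units == "HU" and (self.calibration is None or self.calibration <= 0):
            raise ValueError("HU series require a positive calibration factor")
        if not 0.0 <= self.hematocrit < 1.0:
            raise ValueError(f"hematocrit must be in [0, 1), got {self.hematocrit}")


@dataclass
class PlasmaFitResult:
    """One-compartment fit with residual summary."""

    model: PlasmaDecayModel
    rmse: float       # mgI cm^-3
    r2: float
    n_points: int


@dataclass
class SeriesAnalysis:
    """Everything the transport fit needs, derived from one series."""

    plasma_fit: PlasmaFitResult
    f_v: float
    radius_cm: float
    interstitial_curve: AccumulationCurve   # post-injection, vascular-subtracted
    tumor_curve: AccumulationCurve          # post-injection, total tumor
    blood_curve: AccumulationCurve          # post-injection, whole blood
    plasma_curve: AccumulationCurve         # post-injection, plasma basis


def hu_to_iodine(signal, calibration: float):
    """Convert baseline-subtracted CT enhancement (HU) to mgI cm^-3.

    Linear: concentration = enhancement / calibration.  Mouse scans use
    50.1 HU per mgI cm^-3, rabbit scans 38.0.
    """
    if calibration <= 0:
        raise ValueError(f"calibration must be positive, got {calibration}")
    signal = np.asarray(signal, dtype=float)
    if np.any(signal < 0):
        logger.debug("negative enhancement passed through hu_to_iodine")
    out = signal / calibration
    return out if out.ndim else float(out)


def blood_to_plasma(c_blood, hct: float):
    """Whole-blood to plasma concentration: c / (1 - hct)."""
    if not 0.0 <= hct < 1.0:
        raise ValueError(f"hematocrit must be in [0, 1), got {hct}")
    out = np.asarray(c_blood, dtype=float) / (1.0 - hct)
    return out if out.ndim else float(out)


def fit_one_compartment(curve: AccumulationCurve, refine: bool = True) -> PlasmaFitResult:
    """Fit C_p(t) = c0 * 2^(-t/t_half) to a plasma-basis curve.

    A log-linear least-squares regression provides the estimate (exact
    for noiseless data); an optional nonlinear refinement minimizes the
    untransformed residuals.

    Raises
    ------
    ValueError
        If fewer than two positive-concentration points are available,
        or the data do not decay (non-identifiable half-life).
    """
    mask = (curve.conc > 0) & (curve.times >= 0)
    t = curve.times[mask]
    c = curve.conc[mask]
    if t.size < 2:
        raise ValueError("need at least two positive post-injection points")
    slope, intercept = np.polyfit(t, np.log(c), 1)
    if slope >= 0:
        raise ValueError(
            "plasma data do not decay; half-life is non-identifiable"
        )
    c0 = float(np.exp(intercept))
    t_half = float(np.log(2.0) / -slope)
    if refine and t.size > 2:
        try:
            popt, _ = optimize.curve_fit(
                lambda tt, a, th: a * np.exp2(-tt / th),
                t,
                c,
                p0=[c0, t_half],
                maxfev=2000,
            )
            if popt[0] > 0 and popt[1] > 0:
                c0, t_half = float(popt[0]), float(popt[1])
        except RuntimeError:  # keep the log-linear estimate
            logger.warning("nonlinear PK refinement failed; using log-linear fit")
    model = PlasmaDecayModel(c0=c0, t_half=t_half)
    resid = c - model(t)
    sst = float(np.sum((c - c.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 1.0
    return PlasmaFitResult(
        model=model,
        rmse=float(np.sqrt(np.mean(resid**2))),
        r2=r2,
        n_points=int(t.size),
    )


def estimate_plasma_volume_fraction(
    tumor_conc_early: float, blood_conc_early: float
) -> float:
    """Plasma volume fraction from the first post-injection time point.

    f_v = tumor / blood concentration shortly after injection (5 min in
    mice, 30 min in rabbits), when liposomes are assumed predominantly
    intravascular.
    """
    if blood_conc_early <= 0:
        raise ValueError("blood concentration must be positive")
    ratio = tumor_conc_early / blood_conc_early
    if ratio >= 1.0:
        raise ValueError(
            f"tumor/blood ratio {ratio:.3g} >= 1 is not a plausible vascular fraction"
        )
    if ratio < 0:
        logger.warning("negative early tumor enhancement; clipping f_v to 0")
        return 0.0
    return float(ratio)


def subtract_vascular_contribution(
    tumor: AccumulationCurve, blood: AccumulationCurve, f_v: float
) -> AccumulationCurve:
    """Interstitial curve: tumor(t) - f_v * blood(t), clipped at zero.

    The inverse of :func:`ittm.transport.add_vascular_compartment`.
    """
    if not 0.0 <= f_v < 1.0:
        raise ValueError(f"f_v must be in [0, 1), got {f_v}")
    if tumor.times.shape != blood.times.shape or not np.allclose(
        tumor.times, blood.times, rtol=0, atol=1e-9
    ):
        raise ValueError("tumor and blood curves must share a time axis")
    conc = tumor.conc - f_v * blood.conc
    if np.any(conc < 0):
        logger.warning(
            "vascular subtraction produced %d negative values; clipped to 0",
            int(np.sum(conc < 0)),
        )
        conc = np.clip(conc, 0.0, None)
    return AccumulationCurve(times=tumor.times.copy(), conc=conc, basis="interstitial")


def equivalent_radius(volume: float) -> float:
    """Radius of a sphere with the given volume (same length base).

    R = (3 V / 4 pi)^(1/3); mm^3 gives mm, cm^3 gives cm.
    """
    if volume <= 0:
        raise ValueError(f"volume must be positive, got {volume}")
    return (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)


def analyze_series(series: ImagingSeries, refine: bool = True) -> SeriesAnalysis:
    """Run the full image-based pipeline on one series.

    Baseline (pre-injection) subtraction, HU -> iodine calibration,
    hematocrit correction, one-compartment plasma fit, plasma-volume-
    fraction estimation from the first post-injection point, vascular
    subtraction and equivalent-radius computation.
    """
    t_post = series.times[1:]
    if series.units == "HU":
        tumor_conc = hu_to_iodine(series.tumor[1:] - series.tumor[0], series.calibration)
        blood_conc = hu_to_iodine(series.blood[1:] - series.blood[0], series.calibration)
    else:
        tumor_conc = series.tumor[1:].copy()
        blood_conc = series.blood[1:].copy()
    plasma_conc = blood_to_plasma(blood_conc, series.hematocrit)

    tumor_curve = AccumulationCurve(t_post, np.clip(tumor_conc, 0, None), "total-tumor")
    blood_curve = AccumulationCurve(t_post, np.clip(blood_conc, 0, None), "blood")
    plasma_curve = AccumulationCurve(t_post, np.clip(plasma_conc, 0, None), "plasma")

    plasma_fit = fit_one_compartment(plasma_curve, refine=refine)
    f_v = estimate_plasma_volume_fraction(float(tumor_conc[0]), float(blood_conc[0]))
    interstitial = subtract_vascular_contribution(tumor_curve, blood_curve, f_v)

    if series.volume_mm3 is None:
        raise ValueError("series has no tumor volumes; cannot derive a radius")
    radius_cm = equivalent_radius(float(np.mean(series.volume_mm3))) / 10.0

    return SeriesAnalysis(
        plasma_fit=plasma_fit,
        f_v=f_v,
        radius_cm=radius_cm,
        interstitial_curve=interstitial,
        tumor_curve=tumor_curve,
        blood_curve=blood_curve,
        plasma_curve=plasma_curve,
    )
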