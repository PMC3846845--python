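"""Tumor microenvironment transport parameters.

The model of a spherical tumor with uniform transport properties is
governed by five biophysical parameters plus the tumor radius:

``cfc``
    Capillary filtration coefficient :math:`L_p S/V` (mmHg^-1 s^-1) —
    vascular hydraulic conductivity times vessel surface area per unit
    tissue volume.  Sets the rate of pressure-driven fluid filtration
    out of the vasculature.
``k_int``
    Interstitial hydraulic conductivity :math:`K` (cm^2 mmHg^-1 s^-1) —
    Darcy permeability of the extracellular matrix to fluid flow.
``sigma``
    Filtration reflection coefficient (dimensionless, 0–1): the fraction
    of liposomes rejected at the vessel wall during filtration.
``r_f``
    Retardation coefficient (dimensionless, 0–1]: fractional rate of
    liposome transport relative to interstitial fluid flow.
``p_v``
    Microvascular pressure, MVP (mmHg): the driving pressure for
    transvascular filtration.
``radius``
    Equivalent tumor radius R (cm): radius of a sphere with the same
    volume as the tumor.

The dimensionless group ``alpha = R * sqrt(cfc / k_int)`` is the ratio
of vascular to interstitial permeability to fluid flow.  It controls the
shape of the interstitial fluid pressure (IFP) profile and thereby the
uniform-versus-peripheral character of liposome accumulation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

__all__ = ["TransportParameters", "compute_alpha", "ALPHA_LITERATURE_RANGE"]

#: Range of alpha spanned by published tumor transport properties.
ALPHA_LITERATURE_RANGE = (0.5, 150.0)


def compute_alpha(radius: float, cfc: float, k_int: float) -> float:
    """Dimensionless ratio of vascular to interstitial fluid conductance.

    alpha = R * sqrt(cfc / k_int)

    Parameters
    ----------
    radius : float
        Equivalent tumor radius, cm.
    cfc : float
        Capillary filtration coefficient, mmHg^-1 s^-1.
    k_int : float
        Interstitial hydraulic conductivity, cm^2 mmHg^-1 s^-1.

    Returns
    -------
    float
        alpha (dimensionless).  A :class:`UserWarning` is emitted when the
        value falls outside the range spanned by published tumor transport
        properties (0.5–150); such values are legal but physiologically
        unusual.

    Raises
    ------
    ValueError
        If any argument is non-positive.
    """
    if radius <= 0 or cfc <= 0 or k_int <= 0:
        raise ValueError(
            f"radius, cfc and k_int must all be positive, got "
            f"radius={radius}, cfc={cfc}, k_int={k_int}"
        )
    alpha = radius * math.sqrt(cfc / k_int)
    lo, hi = ALPHA_LITERATURE_RANGE
    if not (lo <= alpha <= hi):
        warnings.warn(
            f"alpha={alpha:.3g} is outside the range {lo}-{hi} reported for "
            "tumor transport properties",
            UserWarning,
            stacklevel=2,
        )
    return alpha


@dataclass(frozen=True)
class TransportParameters:
    """Uniform transport-property set for a spherical tumor."""

    cfc: float
    k_int: float
    p_v: float
    radius: float
    sigma: float = 0.9
    r_f: float = 1.0

    def __post_init__(self) -> None:
        if self.cfc <= 0:
            raise ValueError(f"cfc must be positive, got {self.cfc}")
        if self.k_int <= 0:
            raise ValueError(f"k_int must be positive, got {self.k_int}")
        if not 0.0 <= self.sigma <= 1.0:
            raise ValueError(f"sigma must be in [0, 1], got {self.sigma}")
        if not 0.0 < self.r_f <= 1.0:
            raise ValueError(f"r_f must be in (0, 1], got {self.r_f}")
        if self.p_v <= 0:
            raise ValueError(f"p_v must be positive, got {self.p_v}")
        if self.radius <= 0:
            raise ValueError(f"radius must be positive, got {self.radius}")
        if not math.isfinite(self.alpha):
            raise ValueError("derived alpha is not finite")

    @property
    def alpha(self) -> float:
        """R * sqrt(cfc / k_int), dimensionless."""
        return self.radius * math.sqrt(self.cfc / self.k_int)

    def replace(self, **changes) -> "TransportParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {
            "cfc_per_mmHg_s": self.cfc,
            "k_int_cm2_per_mmHg_s": self.k_int,
            "p_v_mmHg": self.p_v,
            "radius_cm": self.radius,
            "sigma": self.sigma,
            "r_f": self.r_f,
            "alpha": self.alpha,
        }
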