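"""Steady-state interstitial fluid pressure in a spherical tumor.

For a spherically symmetric tumor with uniform transport properties and
no functional intratumoral lymphatics, the steady-state IFP profile has
the closed form

    p_i(r) = p_e * [1 - sinh(alpha * r / R) / ((r / R) * sinh(alpha))]

where ``p_e`` is the effective driving pressure (taken equal to the
microvascular pressure ``p_v``: osmotic terms are omitted and IFP
approaches MVP as alpha grows) and ``alpha = R*sqrt(cfc/k_int)``.
The interstitial fluid velocity follows from Darcy's law,
``u = -K * dp_i/dr``, evaluated analytically.

All sinh ratios are evaluated in a log-domain-stable form so that alpha
up to (and beyond) 150 never overflows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import TransportParameters

__all__ = [
    "PressureField",
    "steady_state_ifp",
    "interstitial_velocity",
    "peak_ifp_ratio",
    "central_ifp_fraction",
    "mean_ifp_fraction",
    "ifp_profile",
]


def _inv_sinh(alpha: float) -> float:
    # 1/sinh(alpha) = 2 e^{-alpha} / (1 - e^{-2 alpha}), stable for large alpha
    return 2.0 * np.exp(-alpha) / (-np.expm1(-2.0 * alpha))


def central_ifp_fraction(alpha: float) -> float:
    """Central IFP as a fraction of the driving pressure: 1 - alpha/sinh(alpha).

    Strictly increasing in alpha, tends to 0 as alpha -> 0 and to 1 as
    alpha -> infinity.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    return float(1.0 - alpha * _inv_sinh(alpha))


def mean_ifp_fraction(alpha: float) -> float:
    """Volume-averaged IFP as a fraction of the driving pressure.

    (3/R^3) * int_0^R p_i(r)/p_e r^2 dr = 1 - 3 (alpha cosh a - sinh a)/(a^2 sinh a).
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    a = alpha
    # (a cosh a - sinh a)/sinh a = a/tanh(a) - 1, with a/tanh stable:
    a_over_tanh = a * (1.0 + np.exp(-2.0 * a)) / (-np.expm1(-2.0 * a))
    return float(1.0 - 3.0 * (a_over_tanh - 1.0) / a**2)


def ifp_profile(alpha: float, p_e: float, x: np.ndarray) -> np.ndarray:
    """IFP at normalized radii ``x = r/R`` in [0, 1].

    The removable singularity at x=0 is evaluated by its analytic limit
    p_e * (1 - alpha/sinh(alpha)); the outer boundary gives exactly 0.
    """
    x = np.asarray(x, dtype=float)
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    p = np.empty_like(x)
    denom = -np.expm1(-2.0 * alpha)
    inner = x > 0
    xi = x[inner]
    # sinh(alpha x)/(x sinh alpha), log-domain stable
    ratio = np.exp(alpha * (xi - 1.0)) * (-np.expm1(-2.0 * alpha * xi)) / (xi * denom)
    p[inner] = p_e * (1.0 - ratio)
    p[~inner] = p_e * central_ifp_fraction(alpha)
    # clamp tiny negative round-off at the rim
    np.clip(p, 0.0, p_e, out=p)
    return p


def _velocity_shape(alpha: float, x: np.ndarray) -> np.ndarray:
    """g(x) = (alpha x cosh(alpha x) - sinh(alpha x)) / (x^2 sinh alpha).

    u(r) = K * p_e / R * g(r/R).  Stable for large alpha; the x -> 0
    cancellation is replaced by its series y^3/3 + y^5/30 (y = alpha x).
    """
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)
    denom = -np.expm1(-2.0 * alpha)
    y = alpha * x
    small = (y < 0.05) & (x > 0)
    large = (y >= 0.05)
    if np.any(large):
        xl, yl = x[large], y[large]
        ecom = np.exp(yl - alpha) / denom
        cosh_ratio = ecom * (1.0 + np.exp(-2.0 * yl))        # cosh(y)/sinh(a)
        sinh_ratio = ecom * (-np.expm1(-2.0 * yl))           # sinh(y)/sinh(a)
        g[large] = (yl * cosh_ratio - sinh_ratio) / xl**2
    if np.any(small):
        xs, ys = x[small], y[small]
        g[small] = (ys**3 / 3.0 + ys**5 / 30.0) * _inv_sinh(alpha) / xs**2
    return g


def interstitial_velocity(
    params: TransportParameters, r: np.ndarray, p_e: float | None = None
) -> np.ndarray:
    """Darcy interstitial fluid velocity u(r) = -K dp_i/dr, cm/s.

    Computed from the analytic derivative of the steady-state pressure
    profile (no numerical differencing).  u(0) = 0 by symmetry; u is
    non-negative (outward) and maximal at r = R.
    """
    if p_e is None:
        p_e = params.p_v
    r = np.asarray(r, dtype=float)
    x = r / params.radius
    return params.k_int * p_e / params.radius * _velocity_shape(params.alpha, x)


def peak_ifp_ratio(params_or_alpha: TransportParameters | float) -> float:
    """Central IFP over MVP, ``p_i(0)/p_v = 1 - alpha/sinh(alpha)``.

    Accepts either a :class:`TransportParameters` or a bare alpha.
    """
    if isinstance(params_or_alpha, TransportParameters):
        alpha = params_or_alpha.alpha
    else:
        alpha = float(params_or_alpha)
    return central_ifp_fraction(alpha)


@dataclass(frozen=True)
class PressureField:
    """Radial IFP and interstitial-velocity profiles on a uniform grid."""

    r_grid: np.ndarray   # cm, ascending, r_grid[0]=0, r_grid[-1]=R
    p_i: np.ndarray      # mmHg
    u: np.ndarray        # cm/s, positive = outward
    p_peak: float        # mmHg, IFP at r=0
    alpha: float
    p_v: float           # mmHg

    @property
    def peak_ratio(self) -> float:
        """p_i(0)/p_v."""
        return self.p_peak / self.p_v

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"r_cm": self.r_grid, "p_mmHg": self.p_i, "u_cm_per_s": self.u}
        )

    def summary(self) -> dict:
        # p_e = p_peak / central_fraction, so the mean ratio rescales the same way
        p_e = self.p_peak / central_ifp_fraction(self.alpha)
        return {
            "alpha": self.alpha,
            "p_peak_mmHg": self.p_peak,
            "ifp_mvp_ratio": self.peak_ratio,
            "mean_ifp_mvp_ratio": mean_ifp_fraction(self.alpha) * p_e / self.p_v,
        }


def steady_state_ifp(
    params: TransportParameters, n_nodes: int = 201, p_e: float | None = None
) -> PressureField:
    """Steady-state IFP and Darcy velocity on a uniform radial grid.

    Parameters
    ----------
    params : TransportParameters
        Tumor transport properties; alpha and R are taken from here.
    n_nodes : int
        Number of uniformly spaced radial nodes (>= 3), including r=0
        and r=R.
    p_e : float, optional
        Effective driving pressure, mmHg.  Defaults to ``params.p_v``.

    Returns
    -------
    PressureField
        With p_i(R) = 0 exactly, p_i non-increasing in r, and u >= 0.
    """
    if n_nodes < 3:
        raise ValueError(f"n_nodes must be >= 3, got {n_nodes}")
    if p_e is None:
        p_e = params.p_v
    alpha = params.alpha
    r = np.linspace(0.0, params.radius, n_nodes)
    x = r / params.radius
    p = ifp_profile(alpha, p_e, x)
    p[-1] = 0.0
    u = params.k_int * p_e / params.radius * _velocity_shape(alpha, x)
    return PressureField(
        r_grid=r, p_i=p, u=u, p_peak=float(p[0]), alpha=alpha, p_v=params.p_v
    )
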