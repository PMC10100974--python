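"""Gompertz growth kinetics and biomass conversion factors.

Anaerobic *Bacteroides* growth is monitored as optical density at 600 nm
(OD600, in absorbance units, "au").  Curves are modelled with the modified
Gompertz equation for bacterial growth,

    OD(t) = A * exp(-exp(k * (lam - t) + 1)),   k = mu_m * e / A,

where ``A`` is the stationary-phase asymptote (au), ``mu_m`` the maximum
specific growth rate (au/h; the slope of the tangent at the inflection
point) and ``lam`` the lag time (h; the x-intercept of that tangent).

OD is linearly related to other biomass proxies (DNA concentration, wet
pellet mass, cell counts); :func:`fit_conversion_factor` estimates those
proportionality constants by ordinary least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "GompertzParams",
    "GrowthCurve",
    "GompertzFit",
    "ConversionFactors",
    "LinearFit",
    "FitError",
    "gompertz_od",
    "fit_gompertz",
    "lag_time_geometry",
    "fit_conversion_factor",
]


class FitError(RuntimeError):
    """Raised when a nonlinear fit fails to converge or the data are degenerate."""


@dataclass(frozen=True)
class GompertzParams:
    """Parameters of the modified Gompertz growth model.

    Attributes
    ----------
    A : float
        Asymptotic OD600 at stationary phase (au).
    mu_m : float
        Maximum specific growth rate (au/h), the tangent slope at the
        curve's inflection point.
    lam : float
        Lag time (h), the x-intercept of the inflection tangent.
    """

    A: float
    mu_m: float
    lam: float

    def __post_init__(self) -> None:
        if not (self.A > 0):
            raise ValueError(f"asymptote A must be positive, got {self.A}")
        if not (self.mu_m > 0):
            raise ValueError(f"growth rate mu_m must be positive, got {self.mu_m}")
        if self.lam < 0:
            raise ValueError(f"lag time lam must be non-negative, got {self.lam}")

    @property
    def k(self) -> float:
        """Derived rate constant k = mu_m * e / A (1/h)."""
        return self.mu_m * math.e / self.A


@dataclass
class GrowthCurve:
    """One OD600 time series (a single well or tube replicate)."""

    times: np.ndarray
    od: np.ndarray
    replicate_id: str = "rep1"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.od.shape:
            raise ValueError("times and od must be 1-D arrays of equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.od < 0):
            raise ValueError("OD values must be non-negative")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class GompertzFit:
    """Result of :func:`fit_gompertz`: parameters plus a residual summary."""

    params: GompertzParams
    sum_sq_residuals: float
    n_points: int

    @property
    def rmse(self) -> float:
        return math.sqrt(self.sum_sq_residuals / self.n_points)


@dataclass(frozen=True)
class ConversionFactors:
    """Linear factors tying OD600 to biomass proxies.

    ``dna_per_od`` in µg DNA·mL⁻¹·au⁻¹, ``pellet_per_od`` in mg wet
    pellet·mL⁻¹·au⁻¹ and ``cells_per_od`` in cells·mL⁻¹·au⁻¹.
    """

    dna_per_od: float
    pellet_per_od: float
    cells_per_od: float

    def __post_init__(self) -> None:
        for name in ("dna_per_od", "pellet_per_od", "cells_per_od"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class LinearFit:
    """Ordinary least-squares slope with goodness of fit."""

    slope: float
    intercept: float
    r_squared: float
    intercept_flagged: bool = field(default=False)


def gompertz_od(params: GompertzParams, t):
    """Evaluate the modified Gompertz curve at time(s) ``t`` (hours).

    Monotone non-decreasing in ``t``; tends to ``A`` as t → ∞ and to 0 as
    t → −∞.  Accepts scalars or arrays.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("time values must be finite")
    out = params.A * np.exp(-np.exp(params.k * (params.lam - t) + 1.0))
    return float(out) if out.ndim == 0 else out


def _gompertz_theta(theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    # theta = (log A, log mu_m, lam); log-parametrisation keeps A, mu_m > 0
    A = np.exp(theta[0])
    mu = np.exp(theta[1])
    k = mu * math.e / A
    return A * np.exp(-np.exp(k * (theta[2] - t) + 1.0))


def fit_gompertz(curve: GrowthCurve) -> GompertzFit:
    """Fit (A, mu_m, lam) to an OD time series by nonlinear least squares.

    A and mu_m are fitted on a log scale (so positivity is structural) and
    lam is bounded below at 0.  Initial values: A₀ = max(OD), mu₀ = the
    steepest finite-difference slope, lam₀ = first time OD exceeds 5 % of
    A₀.  Raises :class:`FitError` on flat curves, too few points, or
    non-convergence.
    """
    if len(curve) < 5:
        raise FitError(f"need at least 5 points to fit, got {len(curve)}")
    t, y = curve.times, curve.od
    if np.ptp(y) <= 1e-12 or np.max(y) <= 0:
        raise FitError("degenerate flat curve: OD carries no growth signal")

    a0 = float(np.max(y))
    slopes = np.diff(y) / np.diff(t)
    mu0 = float(np.max(slopes))
    if mu0 <= 0:
        mu0 = a0 / max(np.ptp(t), 1.0)
    above = t[y > 0.05 * a0]
    lam0 = float(above[0]) if above.size else 0.0
    lam0 = max(lam0, 0.0)

    theta0 = np.array([math.log(a0), math.log(mu0), lam0])
    res = optimize.least_squares(
        lambda th: _gompertz_theta(th, t) - y,
        theta0,
        bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
        max_nfev=2000,
    )
    if not res.success:
        raise FitError(
            f"Gompertz fit did not converge for {curve.replicate_id!r}: "
            f"status {res.status}, message {res.message!r}"
        )
    params = GompertzParams(
        A=float(np.exp(res.x[0])), mu_m=float(np.exp(res.x[1])), lam=float(res.x[2])
    )
    ssr = float(np.sum(res.fun**2))
    return GompertzFit(params=params, sum_sq_residuals=ssr, n_points=len(curve))


def lag_time_geometry(params: GompertzParams) -> tuple[float, float]:
    """Return (inflection time, tangent x-intercept) of the Gompertz curve.

    The inflection sits at t = lam + 1/k where OD = A/e; the tangent there
    has slope mu_m, and its x-intercept equals the lag time lam — the
    geometric definition of the lag phase.
    """
    t_infl = params.lam + 1.0 / params.k
    od_infl = params.A / math.e
    x_intercept = t_infl - od_infl / params.mu_m
    return t_infl, x_intercept


def fit_conversion_factor(od, measure) -> LinearFit:
    """OLS regression of a biomass proxy on OD600; the slope is the factor.

    The intercept is left free; it is flagged when its magnitude exceeds
    10 % of the largest measurement, which usually indicates a blank or
    carry-over problem in the proxy assay.
    """
    od = np.asarray(od, dtype=float)
    measure = np.asarray(measure, dtype=float)
    if od.shape != measure.shape or od.ndim != 1:
        raise ValueError("od and measure must be paired 1-D arrays")
    if od.size < 3:
        raise ValueError(f"need at least 3 paired points, got {od.size}")
    if np.ptp(od) <= 0:
        raise ValueError("zero variance in od: slope is undefined")
    out = stats.linregress(od, measure)
    flagged = abs(out.intercept) > 0.10 * float(np.max(np.abs(measure)))
    return LinearFit(
        slope=float(out.slope),
        intercept=float(out.intercept),
        r_squared=float(out.rvalue**2),
        intercept_flagged=flagged,
    )
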