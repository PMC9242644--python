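"""Four-parameter sigmoid calibration: ratio <-> pH.

The standard curve relates the per-cell mean 488/445 ratio to the clamped
buffer pH via the four-parameter logistic (4PL) form

    R(pH) = r_min + (r_max - r_min) / (1 + 10^(slope_h * (ph50 - pH)))

with floor r_min, ceiling r_max, midpoint ph50 (the dye's apparent pKa) and
base-10 slope slope_h (a base-e slope is the same curve up to a rescaling of
slope_h).  The fit is least squares over per-cell calibration points; the
inverse is analytic.  Ratios at or beyond the fitted asymptotes — where the
dye carries no pH information — are clamped to the calibrated pH range and
flagged rather than dropped, so downstream summaries can report how often the
probe saturated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "CalibrationError",
    "fit_calibration",
    "ratio_from_ph",
    "ph_from_ratio",
]


class CalibrationError(ValueError):
    """Calibration fit failure (too few buffers, non-convergence, non-monotone)."""


@dataclass(frozen=True)
class CalibrationPoint:
    """One cell's mean lysosomal ratio at a clamped buffer pH."""

    buffer_ph: float
    cell_mean_ratio: float

    def __post_init__(self) -> None:
        if self.cell_mean_ratio <= 0:
            raise ValueError("cell_mean_ratio must be > 0")
        if not (2.5 <= self.buffer_ph <= 8.0):
            raise ValueError("buffer_ph outside plausible range [2.5, 8.0]")


def _sigmoid(ph, r_min, r_max, ph50, slope_h):
    return r_min + (r_max - r_min) / (1.0 + 10.0 ** (slope_h * (ph50 - ph)))


@dataclass(frozen=True)
class CalibrationCurve:
    r_min: float
    r_max: float
    ph50: float
    slope_h: float
    valid_range: tuple[float, float]
    fit_rss: float = 0.0
    n_points: int = 0

    def __post_init__(self) -> None:
        if not (self.r_max > self.r_min > 0) or self.slope_h <= 0:
            raise CalibrationError("curve must be increasing: r_max > r_min > 0, slope_h > 0")
        if self.valid_range[1] <= self.valid_range[0]:
            raise CalibrationError("valid_range is degenerate")

    def ratio(self, ph):
        """Forward evaluation R(pH)."""
        ph = np.asarray(ph, dtype=float)
        out = _sigmoid(ph, self.r_min, self.r_max, self.ph50, self.slope_h)
        return float(out) if out.ndim == 0 else out

    def invert(self, ratio: float) -> tuple[float, bool]:
        """Analytic inverse with clamp-and-flag semantics.

        Returns (pH, flagged).  Ratios at or outside (r_min, r_max) map to the
        nearest end of the calibrated pH range with flag=True; in-range ratios
        whose pH falls outside the calibrated range are likewise clamped.
        """
        if not np.isfinite(ratio):
            raise ValueError("ratio must be finite")
        lo, hi = self.valid_range
        if ratio <= self.r_min:
            return lo, True
        if ratio >= self.r_max:
            return hi, True
        ph = self.ph50 - math.log10((self.r_max - self.r_min) / (ratio - self.r_min) - 1.0) / self.slope_h
        if ph < lo:
            return lo, True
        if ph > hi:
            return hi, True
        return ph, False


def ratio_from_ph(curve: CalibrationCurve, ph: float) -> float:
    return curve.ratio(ph)


def ph_from_ratio(curve: CalibrationCurve, ratio: float) -> float:
    """Inverse of the calibration law (clamped; see CalibrationCurve.invert)."""
    ph, _ = curve.invert(ratio)
    return ph


def fit_calibration(points: list[CalibrationPoint]) -> CalibrationCurve:
    """Least-squares 4PL fit over per-cell calibration points.

    Requires >= 4 distinct buffer pH values and >= 8 points in total.
    Initialization: r_min/r_max at the observed ratio extremes, ph50 at the
    interpolated midpoint ratio, slope_h = 1; bounds keep r_min >= 0 and
    slope_h in [0.1, 5].  Raises CalibrationError on failure or if the fitted
    curve is not strictly increasing.
    """
    phs = np.array([p.buffer_ph for p in points], dtype=float)
    ratios = np.array([p.cell_mean_ratio for p in points], dtype=float)
    distinct = np.unique(phs)
    if distinct.size < 4:
        raise CalibrationError("need >= 4 distinct buffer pH values")
    if phs.size < 8:
        raise CalibrationError("need >= 8 calibration points")

    r_lo, r_hi = float(ratios.min()), float(ratios.max())
    # per-buffer mean ratios, in increasing-pH order, for the midpoint guess
    means = np.array([ratios[phs == ph].mean() for ph in distinct])
    target = 0.5 * (r_lo + r_hi)
    if np.all(np.diff(means) > 0):
        ph50_0 = float(np.interp(target, means, distinct))
    else:
        ph50_0 = float(distinct[np.argmin(np.abs(means - target))])
    p0 = [max(r_lo, 1e-6), r_hi, ph50_0, 1.0]
    lower = [0.0, 0.0, distinct.min() - 2.0, 0.1]
    upper = [np.inf, np.inf, distinct.max() + 2.0, 5.0]
    p0 = np.clip(p0, lower, upper)
    try:
        popt, _ = curve_fit(
            _sigmoid, phs, ratios, p0=p0, bounds=(lower, upper),
            xtol=1e-14, ftol=1e-14, gtol=1e-14, maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise CalibrationError(f"calibration fit did not converge: {exc}") from exc
    r_min, r_max, ph50, slope_h = (float(v) for v in popt)
    r_min = max(r_min, 1e-12)  # curve invariant needs r_min strictly positive
    if not (r_max > r_min):
        raise CalibrationError("fitted curve is non-monotonic (r_max <= r_min)")
    rss = float(np.sum((_sigmoid(phs, *popt) - ratios) ** 2))
    return CalibrationCurve(
        r_min=r_min, r_max=r_max, ph50=ph50, slope_h=slope_h,
        valid_range=(float(distinct.min()), float(distinct.max())),
        fit_rss=rss, n_points=int(phs.size),
    )
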