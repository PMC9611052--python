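"""Capillary zone electrophoresis quantification of free siRNA.

Free (non-complexed) siRNA is quantified from dual-wavelength
electropherograms: the siRNA peak area at 260 nm, corrected by its
migration time, is normalized against the internal-standard
(4-methylphthalic anhydride) corrected area at 210 nm,

    ratio = (A260 / T260) / (A210 / T210),

the ratio is converted to concentration through a linear calibration, and
the percent complexed follows as 100 (1 - free / control).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "Electropherogram",
    "NormalizedRatio",
    "CZECalibration",
    "CalibrationResults",
    "peak_area",
    "normalized_ratio",
    "percent_complexed",
]


class TraceError(ValueError):
    """Electropherogram trace/window inconsistency."""


@dataclass(frozen=True)
class Electropherogram:
    """Dual-wavelength trace with analyte and internal-standard windows.

    ``sirna_window`` and ``is_window`` are (t1, t2) migration-time ranges
    in minutes; defaults suit the short-end injection geometry where both
    species elute in under 5 min.
    """

    time_min: np.ndarray
    au260: np.ndarray
    au210: np.ndarray
    sirna_window: tuple[float, float] = (2.6, 3.8)
    is_window: tuple[float, float] = (1.3, 2.3)

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, float)
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "au260", np.asarray(self.au260, float))
        object.__setattr__(self, "au210", np.asarray(self.au210, float))
        if np.any(np.diff(t) <= 0):
            raise TraceError("migration-time grid must be strictly increasing")
        if len(t) != len(self.au260) or len(t) != len(self.au210):
            raise TraceError("traces must match the time grid")
        for name, (a, b) in (("sirna", self.sirna_window), ("is", self.is_window)):
            if a >= b:
                raise TraceError(f"{name} window empty")
            if a < t[0] or b > t[-1]:
                raise TraceError(f"{name} window outside trace")
        lo = max(self.sirna_window[0], self.is_window[0])
        hi = min(self.sirna_window[1], self.is_window[1])
        if lo < hi:
            raise TraceError("analyte and internal-standard windows overlap")


@dataclass(frozen=True)
class NormalizedRatio:
    """Corrected-area ratio (A260/T260)/(A210/T210) and its ingredients."""

    a260: float
    t260: float
    a210: float
    t210: float

    @property
    def ratio(self) -> float:
        if min(self.t260, self.a210, self.t210) <= 0:
            raise TraceError("ratio denominators must be positive")
        return (self.a260 / self.t260) / (self.a210 / self.t210)


def peak_area(
    eg: Electropherogram, window: tuple[float, float], wavelength: int
) -> tuple[float, float]:
    """Baseline-subtracted peak area and apex migration time in a window.

    The baseline is the straight line between the window endpoints, each
    anchored at the mean of the trace over the outer 5% of the window
    (noise-robust endpoint estimate); the area is trapezoidal over the
    baseline.  A negative net area is clipped to 0 with a warning.
    """
    trace = {260: eg.au260, 210: eg.au210}.get(wavelength)
    if trace is None:
        raise TraceError(f"no trace at {wavelength} nm")
    t = eg.time_min
    mask = (t >= window[0]) & (t <= window[1])
    if mask.sum() < 3:
        raise TraceError("window contains too few samples")
    tw, yw = t[mask], trace[mask]
    margin = max(int(0.05 * len(tw)), 1)
    t_lo, y_lo = tw[:margin].mean(), yw[:margin].mean()
    t_hi, y_hi = tw[-margin:].mean(), yw[-margin:].mean()
    base = y_lo + (tw - t_lo) * (y_hi - y_lo) / (t_hi - t_lo)
    net = yw - base
    area = float(np.trapezoid(net, tw))
    if area < 0:
        warnings.warn("negative peak area after baseline; clipped to 0")
        area = 0.0
    apex = float(tw[np.argmax(net)])
    return area, apex


def normalized_ratio(
    eg: Electropherogram, min_is_area: float = 1e-9
) -> NormalizedRatio:
    """Corrected-area ratio of the siRNA peak against the internal standard."""
    a260, t260 = peak_area(eg, eg.sirna_window, 260)
    a210, t210 = peak_area(eg, eg.is_window, 210)
    if a210 <= min_is_area:
        raise TraceError("internal-standard peak missing: quantification impossible")
    return NormalizedRatio(a260=a260, t260=t260, a210=a210, t210=t210)


class CZECalibration:
    """Linear calibration of normalized ratio against siRNA concentration.

    Built from standard-solution measurements, e.g. nine levels between
    0.5 and 8 uM in triplicate.  ``fit()`` runs ordinary least squares and
    returns :class:`CalibrationResults` with slope, intercept, r^2 and the
    inverse map from ratio to concentration.
    """

    def __init__(self, concentrations_uM, ratios):
        c = np.asarray(concentrations_uM, float)
        r = np.asarray(ratios, float)
        if len(c) != len(r):
            raise ValueError("concentrations and ratios must have equal length")
        if len(np.unique(c)) < 2:
            raise ValueError("need at least 2 distinct concentration levels")
        self.concentrations = c
        self.ratios = r

    def fit(self) -> "CalibrationResults":
        res = stats.linregress(self.concentrations, self.ratios)
        return CalibrationResults(
            model=self, slope=res.slope, intercept=res.intercept,
            r_squared=res.rvalue ** 2,
            slope_se=res.stderr, intercept_se=res.intercept_stderr,
        )


@dataclass(frozen=True)
class CalibrationResults:
    model: CZECalibration
    slope: float
    intercept: float
    r_squared: float
    slope_se: float
    intercept_se: float

    @property
    def concentration_range(self) -> tuple[float, float]:
        c = self.model.concentrations
        return float(c.min()), float(c.max())

    def predict(self, concentration_uM):
        return self.slope * np.asarray(concentration_uM, float) + self.intercept

    def invert(self, ratio) -> float | np.ndarray:
        """Free-siRNA concentration (uM) from a normalized ratio."""
        if self.slope == 0:
            raise ValueError("zero calibration slope")
        out = (np.asarray(ratio, float) - self.intercept) / self.slope
        return float(out) if np.ndim(ratio) == 0 else out

    def summary(self) -> str:
        lo, hi = self.concentration_range
        return "\n".join([
            "CZE linear calibration",
            "=" * 40,
            f"ratio = {self.slope:.5g} x conc(uM) + {self.intercept:.5g}",
            f"r^2 = {self.r_squared:.4f}",
            f"range: {lo:g} - {hi:g} uM, {len(self.model.concentrations)} points",
        ])


def percent_complexed(sample_free_uM: float, control_total_uM: float) -> float:
    """Percent of siRNA complexed: 100 (1 - free/control), clipped to [0, 100]."""
    if control_total_uM <= 0:
        raise ValueError("control concentration must be positive")
    if sample_free_uM < 0:
        raise ValueError("free concentration must be nonnegative")
    pct = 100.0 * (1.0 - sample_free_uM / control_total_uM)
    if pct < 0.0 or pct > 100.0:
        warnings.warn(f"percent complexed {pct:.1f} outside [0, 100]; clipped")
    return float(np.clip(pct, 0.0, 100.0))
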