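"""Saturation extrapolation of per-copolymer-count metric series.

As copolymer chains are added around one siRNA, the complexed-copolymer
stoichiometry and the binding enthalpy trend toward saturation.  The
saturation point is operationalized as the stationary point of a degree-2
least-squares polynomial fitted to the series: for value = a x^2 + b x + c
with a < 0, the maximum sits at x* = -b/(2a) and the asymptotic value is
the parabola evaluated there.  Enthalpy series are fitted in kcal/mol and
reported in kJ/mol (x 4.184).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

KJ_PER_KCAL = 4.184

__all__ = [
    "MetricSeries",
    "QuadraticSaturationModel",
    "SaturationResults",
    "fit_quadratic",
]


class SeriesError(ValueError):
    """Series unusable for a quadratic fit."""


@dataclass(frozen=True)
class MetricSeries:
    """Per-copolymer-count metric values with optional SDs."""

    counts: np.ndarray
    values: np.ndarray
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", np.asarray(self.counts, float))
        object.__setattr__(self, "values", np.asarray(self.values, float))
        if len(self.counts) != len(self.values):
            raise SeriesError("counts and values must have equal length")
        if np.any(np.diff(self.counts) <= 0):
            raise SeriesError("copolymer counts must be strictly increasing")
        if self.sd is not None:
            object.__setattr__(self, "sd", np.asarray(self.sd, float))


class QuadraticSaturationModel:
    """Degree-2 saturation model for a metric series.

    ``fit()`` performs an ordinary (unweighted) least-squares quadratic fit
    — exact on noiseless quadratic data — and returns
    :class:`SaturationResults` with the coefficients, the stationary point
    and unit-conversion helpers.
    """

    def __init__(self, series: MetricSeries):
        if len(np.unique(series.counts)) < 3:
            raise SeriesError("need at least 3 distinct copolymer counts")
        self.series = series

    def fit(self) -> "SaturationResults":
        x, y = self.series.counts, self.series.values
        # numpy polynomial OLS; coefficients in ascending order
        coef = np.polynomial.polynomial.polyfit(x, y, 2)
        resid = y - np.polynomial.polynomial.polyval(x, coef)
        return SaturationResults(self, c=coef[0], b=coef[1], a=coef[2],
                                 rss=float(resid @ resid))


class SaturationResults:
    """Fitted quadratic, its stationary point and evaluation helpers."""

    def __init__(self, model, a: float, b: float, c: float, rss: float):
        self.model = model
        self.a, self.b, self.c = float(a), float(b), float(c)
        self.rss = rss

    @property
    def coefficients(self) -> tuple[float, float, float]:
        return self.a, self.b, self.c

    @property
    def is_maximum(self) -> bool:
        return self.a < 0

    def stationary_point(self) -> tuple[float, float]:
        """(x*, value at x*) where the fitted parabola's derivative vanishes.

        Flags via :attr:`is_maximum`; a == 0 has no stationary point.
        """
        scale = max(abs(self.b), abs(self.c), 1.0)
        if abs(self.a) < 1e-10 * scale:
            raise SeriesError("degenerate quadratic (a ~ 0): no stationary point")
        x_star = -self.b / (2.0 * self.a)
        return x_star, self.predict(x_star)

    def predict(self, x, unit_out: str = "model") -> float | np.ndarray:
        """Evaluate the parabola; ``unit_out='kJ'`` converts kcal -> kJ."""
        val = self.a * np.asarray(x, float) ** 2 + self.b * np.asarray(x, float) + self.c
        if unit_out == "kJ":
            val = val * KJ_PER_KCAL
        elif unit_out not in ("model", "kcal"):
            raise ValueError(f"unknown unit_out {unit_out!r}")
        if np.ndim(x) == 0:
            return float(val)
        return val

    def summary(self) -> str:
        x_star, v = self.stationary_point() if self.a != 0 else (np.nan, np.nan)
        kind = "maximum" if self.is_maximum else "minimum"
        return "\n".join([
            "Quadratic saturation fit",
            "=" * 40,
            f"value = a x^2 + b x + c",
            f"a = {self.a:.6g}   b = {self.b:.6g}   c = {self.c:.6g}",
            f"rss = {self.rss:.3g}",
            f"stationary point ({kind}): x* = {x_star:.4g}, value = {v:.4g}",
        ])

    def to_dict(self) -> dict:
        x_star, v = self.stationary_point()
        return {
            "a": self.a, "b": self.b, "c": self.c,
            "x_star": x_star, "value_at_x_star": v,
            "kind": "maximum" if self.is_maximum else "minimum",
            "rss": self.rss,
        }


def fit_quadratic(series: MetricSeries) -> SaturationResults:
    """Convenience wrapper: fit the degree-2 saturation model to a series."""
    return QuadraticSaturationModel(series).fit()
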