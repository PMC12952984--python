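"""Linear cumulative-prevalence fitting with onset-shift estimation.

Under a constant rate of DNA damage, disease incidence among those at
risk is constant and cumulative prevalence grows linearly with age (or
with time since a first diagnosis).  Ordinary least squares on the
linear regime then yields three interpretable quantities: the slope
(incidence, fraction of the at-risk population per year), the x-intercept
(an onset/recognition shift in years) and the extrapolated age at which
the fitted line reaches a cumulative fraction of one — the horizon at
which every at-risk person would have developed the disease.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

__all__ = [
    "PrevalenceSeries",
    "LinearPrevalenceFit",
    "LinearPrevalenceModel",
    "fit_linear_prevalence",
    "incidence_from_prevalence",
]

TIME_KINDS = ("age-at-diagnosis", "interval-since-first-diagnosis")

#: Incidence declines after age ~60 (immune-system ageing); age-based
#: series are fitted up to this age by default.
DEFAULT_AGE_WINDOW_UPPER = 60.0


@dataclass(frozen=True)
class PrevalenceSeries:
    """Cumulative prevalence points (time in years, cumulative fraction).

    ``cumulative`` may be raw case counts; pass ``at_risk`` to normalise
    them to fractions of the at-risk population before fitting or
    extrapolating.
    """

    times: tuple[float, ...]
    cumulative: tuple[float, ...]
    time_kind: str = "age-at-diagnosis"
    label: str = ""

    def __init__(
        self,
        times: Sequence[float],
        cumulative: Sequence[float],
        time_kind: str = "age-at-diagnosis",
        label: str = "",
        at_risk: float | None = None,
    ) -> None:
        t = np.asarray(times, dtype=float)
        c = np.asarray(cumulative, dtype=float)
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("times and cumulative must be 1-D and of equal length")
        if t.size < 2:
            raise ValueError("a prevalence series needs at least two points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.diff(c) < 0):
            raise ValueError("cumulative values must be non-decreasing")
        if at_risk is not None:
            if at_risk <= 0:
                raise ValueError("at_risk denominator must be positive")
            c = c / at_risk
        if np.any(c < 0) or np.any(c > 1):
            raise ValueError(
                "cumulative fractions must lie in [0, 1]; pass at_risk= to normalise counts"
            )
        if time_kind not in TIME_KINDS:
            raise ValueError(f"time_kind must be one of {TIME_KINDS}")
        object.__setattr__(self, "times", tuple(float(x) for x in t))
        object.__setattr__(self, "cumulative", tuple(float(x) for x in c))
        object.__setattr__(self, "time_kind", time_kind)
        object.__setattr__(self, "label", label)

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class LinearPrevalenceFit:
    """OLS line through a cumulative-prevalence series.

    ``onset_shift = -intercept/slope`` (x-intercept, years) and
    ``years_to_full = (1 - intercept)/slope`` (time for the fitted line
    to reach cumulative = 1).  Both are NaN when the slope is not
    positive; ``full_penetrance_defined`` flags that case.
    """

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    window: tuple[float, float] | None = None

    @property
    def onset_shift(self) -> float:
        if self.slope <= 0:
            return float("nan")
        return -self.intercept / self.slope

    @property
    def years_to_full(self) -> float:
        if self.slope <= 0:
            return float("nan")
        return (1.0 - self.intercept) / self.slope

    @property
    def full_penetrance_defined(self) -> bool:
        return self.slope > 0

    def predict(self, times: Sequence[float]) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(times, dtype=float)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "onset_shift": self.onset_shift,
            "years_to_full": self.years_to_full,
            "n_points": self.n_points,
            "window": list(self.window) if self.window else None,
        }

    def summary(self) -> str:
        lines = [
            "Linear cumulative-prevalence fit",
            "=" * 32,
            f"points used:     {self.n_points}" + (f"  (window {self.window[0]:g}-{self.window[1]:g} y)" if self.window else ""),
            f"slope:           {self.slope:.6g} /year",
            f"intercept:       {self.intercept:.6g}",
            f"R^2:             {self.r_squared:.4f}",
            f"onset shift:     {self.onset_shift:.1f} years",
            f"years to full penetrance: {self.years_to_full:.1f}",
        ]
        if not self.full_penetrance_defined:
            lines.append("note: non-positive slope; onset shift and full-penetrance horizon undefined")
        return "\n".join(lines)


class LinearPrevalenceModel:
    """OLS model of cumulative prevalence against time.

    ``window=(lo, hi)`` restricts the fit to points with ``lo <= t <=
    hi``.  For age-at-diagnosis series the default window caps at age 60,
    where incidence starts to decline; interval series are fitted in full
    by default.
    """

    def __init__(
        self,
        series: PrevalenceSeries,
        window: tuple[float, float] | None = None,
    ) -> None:
        if window is None and series.time_kind == "age-at-diagnosis":
            window = (float(min(series.times)), DEFAULT_AGE_WINDOW_UPPER)
        self.series = series
        self.window = window
        t = np.asarray(series.times)
        c = np.asarray(series.cumulative)
        if window is not None:
            lo, hi = window
            keep = (t >= lo) & (t <= hi)
            t, c = t[keep], c[keep]
        if t.size < 3:
            raise ValueError(f"need at least three points in the fitting window, got {t.size}")
        if np.ptp(c) == 0:
            raise ValueError("all cumulative values equal; nothing to fit")
        self._t, self._c = t, c

    def fit(self) -> LinearPrevalenceFit:
        res = sm.OLS(self._c, sm.add_constant(self._t)).fit()
        intercept, slope = res.params
        return LinearPrevalenceFit(
            slope=float(slope),
            intercept=float(intercept),
            r_squared=float(res.rsquared),
            n_points=int(self._t.size),
            window=self.window,
        )


def fit_linear_prevalence(
    series: PrevalenceSeries, window: tuple[float, float] | None = None
) -> LinearPrevalenceFit:
    """Functional wrapper around ``LinearPrevalenceModel(series, window).fit()``."""
    return LinearPrevalenceModel(series, window=window).fit()


def incidence_from_prevalence(series: PrevalenceSeries) -> tuple[np.ndarray, float]:
    """Per-interval incidence (first differences over time gaps) and its CV.

    A constant-incidence process gives equal per-interval values and a
    coefficient of variation of zero; the CV summarises how constant the
    observed incidence is.
    """
    t = np.asarray(series.times)
    c = np.asarray(series.cumulative)
    inc = np.diff(c) / np.diff(t)
    mean = inc.mean()
    cv = float(inc.std(ddof=0) / mean) if mean > 0 else float("inf")
    return inc, cv
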