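"""Geometric event-count model for multiple autoimmune events per person.

The model ("omnipresent neoplasia equations", ONE, in the endoscopy
literature) assumes a constant per-person event chance ``X``: the
probability that a person at risk accrues at least ``p`` events is
``X**p`` (a geometric survival function), so the fraction with exactly
``p`` events is ``X**p * (1 - X)`` untruncated, or ``X**p`` normalised
over a finite support ``0..P`` when the event count is capped.

Worked example at ``X = 0.5``, counting the primary disease as the
first event: 50% of the at-risk population have >= 1 event, 25% have
exactly one (only the primary disease), 12.5% exactly two (one
additional autoimmune disease), 6.25% exactly three (two additional)
and the remaining 6.25% have four or more events.

The statsmodels-style entry point is :class:`OneModel` built from an
:class:`EventDistribution`; ``OneModel.fit`` returns a :class:`OneFit`
with the estimated event chance, expected category counts and fit
diagnostics (Pearson correlation on counts, log10-linear regression).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "EventDistribution",
    "FitDiagnostics",
    "OneFit",
    "OneModel",
    "one_fraction",
    "one_survival",
    "fit_event_chance",
    "pearson_cc",
    "report_pcc",
    "reconstruct_distribution",
    "at_risk_fraction_estimate",
    "PCC_ROUNDING_THRESHOLD",
]

#: Pearson correlations above this reporting threshold are rounded up to 1.
PCC_ROUNDING_THRESHOLD = 0.9995

#: Event-count cap used when normalising the geometric fractions
#: (carried over from the colonoscopy polyp-count convention of >= 12).
DEFAULT_TRUNCATION_P = 12

#: Highest event count displayed in reports (six or more events in one
#: person are rare, so predictions are shown for p = 0..5 only).
DEFAULT_DISPLAY_P = 5

FIT_METHODS = ("loglinear", "survival", "mean", "grid")


class DegenerateDistributionError(ValueError):
    """All observations fall in a single category; X is unidentifiable."""


class RefuseToFitError(ValueError):
    """Fewer than three non-zero categories; any model fits two points."""


def _check_x(X: float) -> float:
    if not (0.0 <= X <= 1.0) or math.isnan(X):
        raise ValueError(f"event chance X must lie in [0, 1], got {X!r}")
    return float(X)


@dataclass(frozen=True)
class EventDistribution:
    """Persons per event-count category.

    Parameters
    ----------
    counts
        Map from event count ``p`` (non-negative int) to the number of
        persons with exactly ``p`` events.
    zero_included
        Whether the ``p = 0`` category is observable.  For zero-truncated
        panels (e.g. additional autoimmune diseases among persons whose
        primary disease is not itself autoimmune) it is not, and model
        fractions are renormalised over ``p >= 1``.
    label
        Free-text description.
    """

    counts: Mapping[int, int]
    zero_included: bool = True
    label: str = ""

    def __post_init__(self) -> None:
        cleaned: dict[int, int] = {}
        for p, n in self.counts.items():
            p = int(p)
            if p < 0:
                raise ValueError(f"event count p must be >= 0, got {p}")
            if n != int(n) or n < 0:
                raise ValueError(f"person count for p={p} must be a non-negative integer, got {n!r}")
            cleaned[p] = cleaned.get(p, 0) + int(n)
        if not cleaned:
            raise ValueError("empty event distribution")
        if not self.zero_included and cleaned.get(0, 0) > 0:
            raise ValueError("zero_included is False but a p=0 category is present")
        object.__setattr__(self, "counts", dict(sorted(cleaned.items())))

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())

    @property
    def n_events(self) -> int:
        return sum(p * n for p, n in self.counts.items())

    @property
    def max_p(self) -> int:
        return max(self.counts)

    def count_vector(self, p_max: int | None = None) -> np.ndarray:
        """Counts over the support (0..p_max or 1..p_max), missing categories as 0."""
        if p_max is None:
            p_max = self.max_p
        lo = 0 if self.zero_included else 1
        return np.array([self.counts.get(p, 0) for p in range(lo, p_max + 1)], dtype=float)

    def support(self, p_max: int | None = None) -> np.ndarray:
        if p_max is None:
            p_max = self.max_p
        lo = 0 if self.zero_included else 1
        return np.arange(lo, p_max + 1)


def one_survival(X: float, p: int) -> float:
    """Fraction of the at-risk population with at least ``p`` events: ``X**p``."""
    X = _check_x(X)
    if p < 0:
        raise ValueError(f"event count p must be >= 0, got {p}")
    if p == 0:
        return 1.0
    return X**p


def one_fraction(X: float, p: int, truncation_P: int | None = None) -> float:
    """Fraction of the at-risk population with exactly ``p`` events.

    Untruncated (``truncation_P=None``): ``X**p * (1 - X)``, the
    difference of consecutive survival values.  Truncated at ``P``:
    ``X**p / sum(X**q for q in 0..P)`` so the fractions over the capped
    support sum to one.
    """
    X = _check_x(X)
    if p < 0:
        raise ValueError(f"event count p must be >= 0, got {p}")
    if truncation_P is None:
        if X == 0.0:
            return 1.0 if p == 0 else 0.0
        return X**p * (1.0 - X)
    P = int(truncation_P)
    if p > P:
        return 0.0
    if X == 0.0:
        return 1.0 if p == 0 else 0.0
    weights = X ** np.arange(0, P + 1)
    return float(X**p / weights.sum())


def _fractions(X: float, support: np.ndarray, truncation_P: int) -> np.ndarray:
    """Model fractions over ``support`` renormalised over support..truncation_P.

    For a zero-truncated panel the support starts at 1 and the
    normalisation runs over ``1..P`` (conditioning on at least one event).
    """
    lo = int(support[0])
    qs = np.arange(lo, truncation_P + 1)
    if X == 0.0:
        w = (qs == 0).astype(float)
        if w.sum() == 0:  # zero-truncated with X=0: conditional mass undefined, put all at p=lo
            w = (qs == lo).astype(float)
    else:
        w = X**qs.astype(float)
    w = w / w.sum()
    out = np.zeros(len(support))
    for i, p in enumerate(support):
        if lo <= p <= truncation_P:
            out[i] = w[p - lo]
    return out


def pearson_cc(observed: Sequence[float], expected: Sequence[float]) -> float:
    """Pearson correlation between observed and model-expected category counts."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape:
        raise ValueError("observed and expected vectors must have equal length")
    if obs.size < 3:
        raise ValueError("Pearson correlation needs at least three categories")
    if np.ptp(obs) == 0 or np.ptp(exp) == 0:
        raise ValueError("undefined correlation: zero variance in one of the vectors")
    return float(stats.pearsonr(obs, exp).statistic)


def report_pcc(pcc: float) -> float:
    """Reporting convention: a PCC above 0.9995 is rounded up to 1."""
    return 1.0 if pcc > PCC_ROUNDING_THRESHOLD else pcc


@dataclass(frozen=True)
class FitDiagnostics:
    """Goodness-of-fit summary for a fitted event-chance model.

    ``pcc`` is the Pearson correlation between observed and expected
    counts on the linear scale over the displayed categories;
    ``log_slope``/``log_intercept``/``r_squared`` come from the simple
    linear regression of log10 observed counts on ``p`` (an exponential
    decay is linear after the log10 transform).
    """

    pcc: float
    log_slope: float
    log_intercept: float
    r_squared: float

    @property
    def pcc_reported(self) -> float:
        return report_pcc(self.pcc)


@dataclass(frozen=True)
class OneFit:
    """Fitted event chance with expected counts and diagnostics."""

    X: float
    method: str
    truncation_P: int
    display_P: int
    distribution: EventDistribution
    diagnostics: FitDiagnostics = field(repr=False)

    @property
    def expected_counts(self) -> dict[int, float]:
        """Expected persons per category over the full truncation range.

        Sums to ``n_total`` (zero-truncated scaling when the zero
        category is unobservable)."""
        dist = self.distribution
        support = dist.support(self.truncation_P)
        fr = _fractions(self.X, support, self.truncation_P)
        return {int(p): float(f * dist.n_total) for p, f in zip(support, fr)}

    def predict(self, p: int) -> float:
        """Model fraction with exactly ``p`` events under the fitted X."""
        return one_fraction(self.X, p, self.truncation_P)

    def to_dict(self) -> dict:
        d = self.diagnostics
        return {
            "X": self.X,
            "method": self.method,
            "truncation_P": self.truncation_P,
            "display_P": self.display_P,
            "n_total": self.distribution.n_total,
            "zero_included": self.distribution.zero_included,
            "expected_counts": {str(k): v for k, v in self.expected_counts.items()},
            "pcc": d.pcc,
            "pcc_reported": d.pcc_reported,
            "log_slope": d.log_slope,
            "log_intercept": d.log_intercept,
            "r_squared": d.r_squared,
        }

    def summary(self) -> str:
        d = self.diagnostics
        lines = [
            "Geometric event-chance model fit",
            "=" * 34,
            f"label:           {self.distribution.label or '(unlabelled)'}",
            f"method:          {self.method}",
            f"event chance X:  {self.X:.4f}",
            f"truncation P:    {self.truncation_P}   display P: {self.display_P}",
            f"persons:         {self.distribution.n_total}   events: {self.distribution.n_events}",
            f"PCC:             {d.pcc:.4f} (reported {d.pcc_reported:g})",
            f"log10 regression: slope {d.log_slope:.4f}, R^2 {d.r_squared:.4f}",
            "",
            f"{'p':>3} {'observed':>9} {'expected':>10}",
        ]
        exp = self.expected_counts
        for p in sorted(exp):
            if p > self.display_P:
                continue
            obs = self.distribution.counts.get(p, 0)
            lines.append(f"{p:>3} {obs:>9d} {exp[p]:>10.2f}")
        return "\n".join(lines)


class OneModel:
    """Geometric event-count model bound to an observed distribution.

    Examples
    --------
    >>> dist = EventDistribution({1: 8, 2: 4, 3: 2, 4: 1}, zero_included=False)
    >>> fit = OneModel(dist).fit(method="loglinear")
    >>> round(fit.X, 6)
    0.5
    """

    def __init__(
        self,
        distribution: EventDistribution,
        truncation_P: int = DEFAULT_TRUNCATION_P,
        display_P: int = DEFAULT_DISPLAY_P,
    ) -> None:
        if truncation_P < 1:
            raise ValueError("truncation_P must be >= 1")
        if distribution.max_p > truncation_P:
            raise ValueError(
                f"observed category p={distribution.max_p} exceeds truncation_P={truncation_P}"
            )
        self.distribution = distribution
        self.truncation_P = int(truncation_P)
        self.display_P = int(display_P)

    # -- estimators -----------------------------------------------------

    def _estimate(self, method: str) -> float:
        dist = self.distribution
        nonzero = {p: n for p, n in dist.counts.items() if n > 0}
        if len(nonzero) < 3:
            raise RefuseToFitError(
                f"need at least three non-zero categories to fit, got {len(nonzero)} "
                "(any model fits two points)"
            )
        if len({p for p in nonzero}) == 1:
            raise DegenerateDistributionError("all persons fall in one category")
        if method == "loglinear":
            ps = np.array(sorted(nonzero))
            logn = np.log10([nonzero[p] for p in sorted(nonzero)])
            if np.ptp(logn) == 0:  # flat counts: slope 0 -> X = 1
                return 1.0
            res = stats.linregress(ps, logn)
            return float(min(max(10**res.slope, 0.0), 1.0))
        if method == "survival":
            if not dist.zero_included:
                raise ValueError("survival estimator needs the p=0 category (zero_included)")
            n0 = dist.counts.get(0, 0)
            return (dist.n_total - n0) / dist.n_total
        if method == "mean":
            lo = 0 if dist.zero_included else 1
            target = dist.n_events / dist.n_total
            qs = np.arange(lo, self.truncation_P + 1)

            def mean_of(X: float) -> float:
                w = X ** qs.astype(float)
                return float((qs * w).sum() / w.sum())

            if target <= mean_of(1e-12):
                return 0.0
            if target >= mean_of(1 - 1e-12):
                return 1.0
            return float(optimize.brentq(lambda X: mean_of(X) - target, 1e-12, 1 - 1e-12))
        if method == "grid":
            # least squares between observed counts and the geometric
            # profile renormalised over the observed support, so that an
            # exactly geometric table is recovered exactly
            support = dist.support()
            obs = dist.count_vector()
            grid = np.arange(1e-4, 1.0, 1e-4)
            w = grid[:, None] ** support[None, :].astype(float)
            exp = dist.n_total * w / w.sum(axis=1, keepdims=True)
            sse = ((exp - obs[None, :]) ** 2).sum(axis=1)
            return float(grid[int(np.argmin(sse))])
        raise ValueError(f"unknown method {method!r}; choose from {FIT_METHODS}")

    def fit(self, method: str = "loglinear") -> OneFit:
        """Estimate the event chance X and assemble diagnostics.

        Methods: ``loglinear`` (slope of log10 counts vs p; the default),
        ``survival`` (fraction with >= 1 event; needs the zero category),
        ``mean`` (matches the truncated-geometric mean event count) and
        ``grid`` (least-squares over X in (0,1) at step 1e-4).
        """
        X = self._estimate(method)
        dist = self.distribution
        # diagnostics over the displayed categories
        p_hi = min(max(dist.max_p, 3), self.display_P if dist.max_p <= self.display_P else dist.max_p)
        support = dist.support(p_hi)
        obs = dist.count_vector(p_hi)
        exp = _fractions(X, support, self.truncation_P) * dist.n_total
        try:
            pcc = pearson_cc(obs, exp)
        except ValueError:
            pcc = float("nan")
        pos = obs > 0
        if pos.sum() >= 3 and np.ptp(np.log10(obs[pos])) > 0:
            reg = stats.linregress(support[pos], np.log10(obs[pos]))
            log_slope, log_intercept, r2 = float(reg.slope), float(reg.intercept), float(reg.rvalue**2)
        else:
            log_slope = log_intercept = r2 = float("nan")
        diag = FitDiagnostics(pcc=pcc, log_slope=log_slope, log_intercept=log_intercept, r_squared=r2)
        return OneFit(
            X=X,
            method=method,
            truncation_P=self.truncation_P,
            display_P=self.display_P,
            distribution=dist,
            diagnostics=diag,
        )


def fit_event_chance(
    dist: EventDistribution,
    method: str = "loglinear",
    truncation_P: int = DEFAULT_TRUNCATION_P,
    display_P: int = DEFAULT_DISPLAY_P,
) -> OneFit:
    """Functional wrapper around ``OneModel(dist, ...).fit(method)``."""
    return OneModel(dist, truncation_P=truncation_P, display_P=display_P).fit(method)


def at_risk_fraction_estimate(frac_with_events: float) -> float:
    """Fraction of the at-risk population with zero events: the complement.

    Shifting the observed curve one event to the right (the disease under
    study counts as the first event) makes the zero-event at-risk group
    estimable as ``1 - frac_with_events``.
    """
    if not (0.0 <= frac_with_events <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    return 1.0 - frac_with_events


def _enumerate_nonincreasing(n_cases: int, n_events: int, max_p: int) -> list[tuple[int, ...]]:
    """All non-increasing integer vectors n_1..n_max_p with the two totals."""
    out: list[tuple[int, ...]] = []

    def rec(idx: int, rem_c: int, rem_e: int, prev: int, acc: list[int]) -> None:
        if idx == max_p:
            if rem_c == 0 and rem_e == 0:
                out.append(tuple(acc))
            return
        weight = idx + 1
        # remaining events bounded by rem_c*weight..rem_c*max_p guides pruning
        for v in range(min(prev, rem_c), -1, -1):
            rem_e2 = rem_e - v * weight
            if rem_e2 < 0:
                continue
            if rem_e2 > (rem_c - v) * max_p:
                continue
            rec(idx + 1, rem_c - v, rem_e2, v, acc + [v])

    rec(0, n_cases, n_events, n_cases, [])
    return out


def reconstruct_distribution(
    n_cases: int,
    n_events: int,
    max_p: int,
    truncation_P: int = DEFAULT_TRUNCATION_P,
) -> dict[int, int]:
    """Recover an integer per-count distribution from its two totals.

    Some studies print only the number of persons with >= 1 event and the
    total event count.  This searches all non-increasing integer vectors
    ``n_1..n_max_p`` with ``sum(n_p) = n_cases`` and ``sum(p*n_p) =
    n_events`` and returns the one closest (least squared deviation) to
    its own best-fitting zero-truncated geometric profile; ties are
    broken by lexicographically largest ``n_1, n_2, ...``.
    """
    if n_cases < 1 or n_events < n_cases:
        raise ValueError("need n_events >= n_cases >= 1")
    if max_p < math.ceil(n_events / n_cases):
        raise ValueError(f"max_p={max_p} cannot accommodate mean event count {n_events / n_cases:.2f}")
    if n_events > n_cases * max_p:
        raise ValueError("infeasible totals: n_events exceeds n_cases * max_p")
    candidates = _enumerate_nonincreasing(n_cases, n_events, max_p)
    if not candidates:
        raise ValueError("infeasible totals: no non-increasing integer vector matches")
    # precompute expected-count matrix over the X grid once (shared n_total)
    grid = np.arange(1e-4, 1.0, 1e-4)
    qs = np.arange(1, truncation_P + 1, dtype=float)
    w = grid[:, None] ** qs[None, :]
    exp_mat = n_cases * w / w.sum(axis=1, keepdims=True)  # (n_grid, P)
    exp_head = exp_mat[:, :max_p]

    def score(vec: tuple[int, ...]) -> float:
        v = np.asarray(vec, dtype=float)
        return float(((exp_head - v) ** 2).sum(axis=1).min())

    best = min(candidates, key=lambda v: (score(v), tuple(-x for x in v)))
    return {p + 1: n for p, n in enumerate(best)}
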