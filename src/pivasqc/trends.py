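"""Longitudinal analysis of a facility panel.

Yearly mean ± SD summaries per indicator/category/total, Shapiro–Wilk
normality checks, and pairwise year comparisons via a paired sign-flip
permutation test (a transparent substitute for generalized estimating
equations on small non-normal panels; results are method-tagged).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .rubric import CATEGORIES, ScoreCard

__all__ = [
    "TrendTable",
    "ComparisonResult",
    "yearly_summary",
    "normality_check",
    "pairwise_compare",
    "compare_years",
]

#: below this many sign patterns the permutation null is enumerated exactly
EXACT_ENUMERATION_LIMIT = 200_000
DEFAULT_PERMUTATIONS = 100_000


@dataclass(frozen=True)
class Cell:
    mean: float
    sd: float
    n: int

    def __str__(self) -> str:
        return f"{self.mean:.2f} ± {self.sd:.2f}"


@dataclass
class TrendTable:
    """Mean ± SD per measure (indicator, category or total) per year."""

    panel_id: str
    years: list[int]
    cells: dict[tuple[str, int], Cell]  # (measure, year) -> Cell
    measures: list[str]

    def cell(self, measure: str, year: int) -> Cell:
        return self.cells[(measure, year)]

    def to_frame(self) -> pd.DataFrame:
        """Wide table: one row per measure, mean/sd/display columns per year."""
        rows = []
        for m in self.measures:
            row: dict[str, Any] = {"measure": m}
            for y in self.years:
                c = self.cells[(m, y)]
                row[f"mean_{y}"] = c.mean
                row[f"sd_{y}"] = c.sd
                row[f"display_{y}"] = str(c)
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ComparisonResult:
    measure: str
    year_a: int
    year_b: int
    effect: float            # mean within-facility difference, B - A
    standard_error: float    # SE of the mean difference
    p_value: float
    n: int
    method: str
    zero_variance: bool = False

    def to_dict(self) -> dict[str, Any]:
        return {
            "measure": self.measure,
            "year_pair": f"{self.year_a}vs{self.year_b}",
            "effect": self.effect,
            "standard_error": self.standard_error,
            "p_value": self.p_value,
            "n": self.n,
            "method": self.method,
            "zero_variance": self.zero_variance,
        }


def _panel_frame(cards: Sequence[ScoreCard]) -> pd.DataFrame:
    rows = []
    for c in cards:
        row: dict[str, Any] = {"facility_id": c.facility_id, "year": c.period.year}
        for ind_id, sc in c.indicators.items():
            row[ind_id] = sc.points
        for cat, v in c.category_subtotals.items():
            row[cat] = v
        row["total"] = c.total
        rows.append(row)
    return pd.DataFrame(rows)


def yearly_summary(cards: Sequence[ScoreCard], panel_id: str = "panel",
                   allow_unbalanced: bool = False) -> TrendTable:
    """Exact mean and n−1 SD per indicator/category/total per year.

    The panel must contain one card per facility per year (a balanced
    panel) unless ``allow_unbalanced`` is set.
    """
    if not cards:
        raise ValueError("empty panel")
    df = _panel_frame(cards)
    years = sorted(df["year"].unique())
    facilities_by_year = {y: set(df.loc[df["year"] == y, "facility_id"]) for y in years}
    balanced = len(set(map(frozenset, facilities_by_year.values()))) == 1
    if not balanced and not allow_unbalanced:
        raise ValueError(
            "unbalanced panel: facilities differ across years "
            f"({ {y: len(f) for y, f in facilities_by_year.items()} }); "
            "pass allow_unbalanced=True to proceed"
        )

    measures = [c for c in df.columns if c not in ("facility_id", "year")]
    cells: dict[tuple[str, int], Cell] = {}
    for y in years:
        sub = df[df["year"] == y]
        for m in measures:
            vals = sub[m].to_numpy(dtype=float)
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            cells[(m, y)] = Cell(mean=float(np.mean(vals)), sd=sd, n=len(vals))
    return TrendTable(panel_id=panel_id, years=[int(y) for y in years],
                      cells=cells, measures=measures)


def normality_check(values: Sequence[float]) -> tuple[float | None, float | None, str]:
    """Shapiro–Wilk test; returns ``(statistic, p, flag)``.

    Constant input cannot be tested and is flagged rather than raising.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise ValueError(f"need at least 3 observations, got {arr.size}")
    if np.ptp(arr) == 0:
        return None, None, "constant"
    stat, p = stats.shapiro(arr)
    return float(stat), float(p), "ok"


_SIGN_CACHE: dict[int, np.ndarray] = {}


def _sign_matrix(n: int) -> np.ndarray:
    """All 2**n sign patterns as a (2**n, n) array of ±1 (cached)."""
    if n not in _SIGN_CACHE:
        bits = (np.arange(2 ** n)[:, None] >> np.arange(n)) & 1
        _SIGN_CACHE[n] = (1.0 - 2.0 * bits).astype(float)
    return _SIGN_CACHE[n]


def pairwise_compare(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
    measure: str = "total",
    year_a: int = 0,
    year_b: int = 1,
) -> ComparisonResult:
    """Paired sign-flip permutation test on the mean within-facility difference.

    The null distribution flips the sign of each facility's difference; the
    two-sided p-value is the fraction of sign patterns whose absolute mean
    difference is at least the observed one. All ``2**n`` patterns are
    enumerated when that is at most :data:`EXACT_ENUMERATION_LIMIT`;
    otherwise ``n_permutations`` random patterns are drawn (seeded, with the
    identity pattern included so p is never zero).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired score vectors must be 1-D and equal length")
    n = a.size
    if n == 0:
        raise ValueError("empty panel")
    diffs = b - a
    effect = float(np.mean(diffs))
    se = float(np.std(diffs, ddof=1) / math.sqrt(n)) if n > 1 else 0.0

    if np.all(diffs == 0):
        return ComparisonResult(measure, year_a, year_b, 0.0, 0.0, 1.0, n,
                                method="sign-flip-permutation", zero_variance=True)

    obs = abs(effect)
    tol = 1e-12 * max(1.0, obs)
    if 2 ** n <= EXACT_ENUMERATION_LIMIT:
        signs = _sign_matrix(n)
        perm_means = np.abs(signs @ diffs) / n
        p = float(np.mean(perm_means >= obs - tol))
        method = "sign-flip-permutation-exact"
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice((1.0, -1.0), size=(n_permutations, n))
        perm_means = np.abs(signs @ diffs) / n
        hits = int(np.sum(perm_means >= obs - tol))
        p = (hits + 1) / (n_permutations + 1)  # identity pattern included
        method = "sign-flip-permutation-mc"
    return ComparisonResult(measure, year_a, year_b, effect, se, p, n, method=method)


def compare_years(
    cards: Sequence[ScoreCard],
    measures: Sequence[str] | None = None,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
    holm: bool = False,
) -> list[ComparisonResult]:
    """All pairwise year comparisons for each measure over a balanced panel.

    Cards are paired by facility. ``measures`` defaults to the 20 indicators,
    the 5 categories and the total. With ``holm=True`` a Holm step-down
    adjustment is applied within each measure's set of year pairs
    (off by default: the reference output reports unadjusted p-values).
    """
    df = _panel_frame(cards)
    years = sorted(int(y) for y in df["year"].unique())
    if measures is None:
        measures = [c for c in df.columns if c not in ("facility_id", "year")]
    results: list[ComparisonResult] = []
    for measure in measures:
        per_measure: list[ComparisonResult] = []
        for ya, yb in itertools.combinations(years, 2):
            wa = df[df["year"] == ya].sort_values("facility_id")
            wb = df[df["year"] == yb].sort_values("facility_id")
            if list(wa["facility_id"]) != list(wb["facility_id"]):
                raise ValueError(f"panel not paired by facility for years {ya}/{yb}")
            per_measure.append(
                pairwise_compare(
                    wa[measure].to_numpy(), wb[measure].to_numpy(),
                    n_permutations=n_permutations, seed=seed,
                    measure=measure, year_a=ya, year_b=yb,
                )
            )
        if holm:
            per_measure = _holm_adjust(per_measure)
        results.extend(per_measure)
    return results


def _holm_adjust(results: list[ComparisonResult]) -> list[ComparisonResult]:
    order = sorted(range(len(results)), key=lambda i: results[i].p_value)
    m = len(results)
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * results[idx].p_value))
        adjusted[idx] = running
    out = []
    for r, p_adj in zip(results, adjusted):
        out.append(ComparisonResult(r.measure, r.year_a, r.year_b, r.effect,
                                    r.standard_error, p_adj, r.n,
                                    method=r.method + "+holm", zero_variance=r.zero_variance))
    return out


def comparisons_to_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])
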