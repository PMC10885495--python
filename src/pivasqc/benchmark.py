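"""Regional aggregation of scorecards: min/mean/max, attainment, radar data."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

from .rubric import CATEGORIES, IndicatorSpec, ScoreCard

__all__ = [
    "StatEntry",
    "RegionalBenchmark",
    "RadarDataset",
    "aggregate_region",
    "attainment_rate",
    "format_attainment",
    "radar_data",
]


@dataclass(frozen=True)
class StatEntry:
    mean: float
    max: float
    min: float
    n: int
    sd: float | None = None

    def __post_init__(self) -> None:
        eps = 1e-9
        if not (self.min - eps <= self.mean <= self.max + eps):
            raise ValueError(f"inconsistent entry: min {self.min}, mean {self.mean}, max {self.max}")


@dataclass
class RegionalBenchmark:
    """Cohort-level summary: per-indicator mean/max/min plus category/total spread."""

    cohort_id: str
    rubric_version: str
    n: int
    indicators: dict[str, StatEntry]
    categories: dict[str, StatEntry]
    total: StatEntry
    #: facility ids that had at least one indicator zeroed for undefined inputs
    lenient_zeroed: list[str] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        def entry(e: StatEntry) -> dict[str, Any]:
            d = {"mean": e.mean, "max": e.max, "min": e.min, "n": e.n}
            if e.sd is not None:
                d["sd"] = e.sd
            return d

        return {
            "cohort_id": self.cohort_id,
            "rubric_version": self.rubric_version,
            "n": self.n,
            "indicators": {k: entry(v) for k, v in self.indicators.items()},
            "categories": {k: entry(v) for k, v in self.categories.items()},
            "total": entry(self.total),
            "lenient_zeroed": list(self.lenient_zeroed),
        }


def _mean(values: Sequence[float]) -> float:
    # fsum is exactly rounded, so aggregation is permutation-invariant
    return math.fsum(values) / len(values)


def _sd(values: Sequence[float]) -> float:
    n = len(values)
    if n < 2:
        return 0.0
    mean = _mean(values)
    return math.sqrt(math.fsum((v - mean) ** 2 for v in values) / (n - 1))


def aggregate_region(cards: Sequence[ScoreCard], cohort_id: str = "region") -> RegionalBenchmark:
    """Exact arithmetic mean/max/min per indicator over a cohort of scorecards.

    Standard deviations (n−1 denominator) are reported for category subtotals
    and the total. All cards must share a rubric version.
    """
    if not cards:
        raise ValueError("need at least one scorecard")
    versions = {c.rubric_version for c in cards}
    if len(versions) != 1:
        raise ValueError(f"mixed rubric versions in cohort: {sorted(versions)}")

    n = len(cards)
    ind_ids = list(cards[0].indicators)
    indicators: dict[str, StatEntry] = {}
    for ind_id in ind_ids:
        vals = [c.indicators[ind_id].points for c in cards]
        indicators[ind_id] = StatEntry(_mean(vals), max(vals), min(vals), n)

    categories: dict[str, StatEntry] = {}
    for cat in CATEGORIES:
        vals = [c.category_subtotals[cat] for c in cards]
        categories[cat] = StatEntry(_mean(vals), max(vals), min(vals), n, sd=_sd(vals))

    totals = [c.total for c in cards]
    total = StatEntry(_mean(totals), max(totals), min(totals), n, sd=_sd(totals))

    zeroed = sorted({c.facility_id for c in cards if c.annotations})
    return RegionalBenchmark(
        cohort_id=cohort_id,
        rubric_version=cards[0].rubric_version,
        n=n,
        indicators=indicators,
        categories=categories,
        total=total,
        lenient_zeroed=zeroed,
    )


def attainment_rate(mean_score: float, spec: IndicatorSpec) -> float:
    """Mean score as a percentage of the indicator maximum (unrounded)."""
    if spec.max_points <= 0:
        raise ValueError(f"indicator {spec.id} has non-positive maximum")
    return 100.0 * mean_score / spec.max_points


def format_attainment(value: float) -> str:
    """Render an attainment percentage in mixed precision.

    Values within 0.05 of an integer print as whole percents, everything
    else to one decimal.
    """
    nearest = round(value)
    if abs(value - nearest) < 0.05:
        return f"{nearest:.0f}%"
    return f"{value:.1f}%"


@dataclass
class RadarDataset:
    """Per-axis series normalized to [0, 1] by indicator (or category) max."""

    axes: list[str]
    own: list[float]
    regional_mean: list[float]
    regional_max: list[float]

    def __post_init__(self) -> None:
        for series in (self.own, self.regional_mean, self.regional_max):
            if len(series) != len(self.axes):
                raise ValueError("series length does not match axes")
            if any(not (0.0 <= v <= 1.0 + 1e-9) for v in series):
                raise ValueError("normalized radar values must lie in [0, 1]")

    def to_dict(self) -> dict[str, Any]:
        return {
            "axes": list(self.axes),
            "own": list(self.own),
            "regional_mean": list(self.regional_mean),
            "regional_max": list(self.regional_max),
        }


def radar_data(
    card: ScoreCard,
    bench: RegionalBenchmark,
    maxima: Mapping[str, float],
    by: str = "indicator",
) -> RadarDataset:
    """Build the radar-chart dataset for one facility against the region.

    ``by="indicator"`` uses the 20 indicator axes; ``by="category"`` the 5
    category axes. ``maxima`` comes from :func:`pivasqc.rubric.rubric_maxima`.
    """
    if card.rubric_version != bench.rubric_version:
        raise ValueError("scorecard and benchmark use different rubric versions")
    if by == "indicator":
        axes = list(card.indicators)
        own = [card.indicators[a].points / maxima[a] for a in axes]
        mean = [bench.indicators[a].mean / maxima[a] for a in axes]
        mx = [bench.indicators[a].max / maxima[a] for a in axes]
    elif by == "category":
        axes = list(CATEGORIES)
        subs = card.category_subtotals
        own = [subs[a] / maxima[a] for a in axes]
        mean = [bench.categories[a].mean / maxima[a] for a in axes]
        mx = [bench.categories[a].max / maxima[a] for a in axes]
    else:
        raise ValueError(f"unknown radar axis mode {by!r}")
    return RadarDataset(axes=axes, own=own, regional_mean=mean, regional_max=mx)
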