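"""The 20-indicator evaluation matrix.

Raw submissions are condensed into :class:`DerivedMetrics`, which the
indicator branch tables consume together with a :class:`RegionalReference`
(province-level averages several branches compare against). Scores roll up
as::

    hardware (11) + personnel (14) + work_efficiency (49)
    + infection_control (13) + information (13) = 100

Branch boundaries follow the published wording: strict ``>`` where the text
says "more than"/"higher than", with the closed end on the lower branch.
Ratios with zero denominators become undefined markers and are never silent
zeros; under the default lenient policy an indicator with undefined inputs
scores 0 and is annotated on the scorecard, under the strict policy it
raises :class:`ScoringError`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any, Callable, Mapping, Sequence

from .schema import Submission, SubmissionSchema, default_schema, match_tokens

__all__ = [
    "UNDEFINED",
    "Undefined",
    "DerivedMetrics",
    "RegionalReference",
    "IndicatorSpec",
    "IndicatorScore",
    "RubricSpec",
    "ScoreCard",
    "ScoringError",
    "derive_metrics",
    "score_indicator",
    "score_submission",
    "rubric_maxima",
    "default_rubric",
    "rubric_from_config",
    "rubric_to_config",
    "CATEGORIES",
    "CATEGORY_MAXIMA",
]

RUBRIC_VERSION = "1.0.0"

HARDWARE = "hardware"
PERSONNEL = "personnel"
WORK_EFFICIENCY = "work_efficiency"
INFECTION_CONTROL = "infection_control"
INFORMATION = "information"

CATEGORIES = (HARDWARE, PERSONNEL, WORK_EFFICIENCY, INFECTION_CONTROL, INFORMATION)
CATEGORY_MAXIMA = {
    HARDWARE: 11,
    PERSONNEL: 14,
    WORK_EFFICIENCY: 49,
    INFECTION_CONTROL: 13,
    INFORMATION: 13,
}


class Undefined:
    """Marker for a metric whose inputs are missing or divide by zero."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNDEFINED"

    def __bool__(self) -> bool:
        return False


UNDEFINED = Undefined()


def is_defined(value: Any) -> bool:
    return value is not UNDEFINED and value is not None


class ScoringError(ValueError):
    """Raised under the strict policy when required inputs are unresolved."""


class _UndefinedInput(Exception):
    def __init__(self, names: list[str]):
        self.names = names
        super().__init__(", ".join(names))


@dataclass(frozen=True)
class DerivedMetrics:
    """Per-submission quantities the branch tables consume.

    All ratios are fractions except ``unreasonable_rate`` which is a
    percentage (it is reported as one).
    """

    m_daily: Any = UNDEFINED            # D05 + D15, bags/day
    consoles: Any = UNDEFINED           # B05 + B08 + B12, double operator consoles
    training_ratio: Any = UNDEFINED     # (C02 + C07) / (C03 + C08)
    pharmacist_prop: Any = UNDEFINED    # C10 / (C10 + C06)
    bed_infusion: Any = UNDEFINED       # D10 / (B10 * days in period), bags/bed/day
    groups_per_syringe: Any = UNDEFINED # D01 / D09
    temp_rate: Any = UNDEFINED          # D15 / D05
    disposition_rate: Any = UNDEFINED   # D17 / D06
    error_rate: Any = UNDEFINED         # (D08 + D18 + D19) / D01
    unreasonable_rate: Any = UNDEFINED  # D16, percent
    equipment_count: Any = UNDEFINED    # distinct automatic-equipment kinds in F01
    traceable_count: Any = UNDEFINED    # kinds flagged traceability-capable
    disinfection_methods: Any = UNDEFINED  # distinct methods parsed from E11


def _ratio(num: Any, den: Any) -> Any:
    if num is None or den is None:
        return UNDEFINED
    if den == 0:
        return UNDEFINED
    return num / den


def _sum(*vals: Any) -> Any:
    if any(v is None for v in vals):
        return UNDEFINED
    return sum(vals)


def derive_metrics(sub: Submission, schema: SubmissionSchema | None = None) -> DerivedMetrics:
    """Compute every derived metric from its defining item formula."""
    schema = schema or default_schema()
    g = sub.get

    unreasonable = g("D16")
    if unreasonable is None:
        unreasonable = _ratio(g("D06"), g("D14"))
        if is_defined(unreasonable):
            unreasonable = 100.0 * unreasonable

    equipment_count = UNDEFINED
    traceable_count = UNDEFINED
    if g("F01") is not None:
        raw = str(g("F01")).strip().lower()
        if raw in ("none", "-"):  # explicit "no automatic equipment"
            equipment_count = 0
            traceable_count = 0
        else:
            vocab = schema.vocabularies["equipment"]
            known, unknown = match_tokens(g("F01"), vocab)
            equipment_count = len(known) + len(set(unknown))
            traceable_count = sum(1 for k in known if k in vocab.traceable)

    methods = UNDEFINED
    if g("E11") is not None:
        vocab = schema.vocabularies["disinfection"]
        known, unknown = match_tokens(g("E11"), vocab)
        # unknown tokens collectively count as one extra method
        methods = len(known) + (1 if unknown else 0)

    # D10 is a per-period flow; normalizing by the period length keeps the
    # bags/bed/day reading identical for quarterly and annual records
    bed_infusion = UNDEFINED
    if g("D10") is not None and g("B10") not in (None, 0):
        bed_infusion = g("D10") / (g("B10") * sub.period.days)

    return DerivedMetrics(
        m_daily=_sum(g("D05"), g("D15")),
        consoles=_sum(g("B05"), g("B08"), g("B12")),
        training_ratio=_ratio(_sum(g("C02"), g("C07")), _sum(g("C03"), g("C08"))),
        pharmacist_prop=_ratio(g("C10"), _sum(g("C10"), g("C06"))),
        bed_infusion=bed_infusion,
        groups_per_syringe=_ratio(g("D01"), g("D09")),
        temp_rate=_ratio(g("D15"), g("D05")),
        disposition_rate=_ratio(g("D17"), g("D06")),
        error_rate=_ratio(_sum(g("D08"), g("D18"), g("D19")), g("D01")),
        unreasonable_rate=unreasonable if unreasonable is not None else UNDEFINED,
        equipment_count=equipment_count,
        traceable_count=traceable_count,
        disinfection_methods=methods,
    )


# ---------------------------------------------------------------------------
# regional reference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionalReference:
    """Province-level averages used by the comparative branch tables.

    ``avg_unreasonable_rate`` is a percentage; the other rates are fractions.
    ``provenance`` records whether the values were configured or derived
    from the scored cohort itself.
    """

    avg_daily_deployment: float
    avg_bed_infusion: float
    avg_groups_per_syringe: float
    avg_unreasonable_rate: float
    avg_disposition_rate: float
    avg_error_rate: float
    provenance: str = "configured"

    def __post_init__(self) -> None:
        for name in (
            "avg_daily_deployment",
            "avg_bed_infusion",
            "avg_groups_per_syringe",
            "avg_unreasonable_rate",
            "avg_disposition_rate",
            "avg_error_rate",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"regional reference {name} must be positive")

    @classmethod
    def from_cohort(
        cls, subs: Sequence[Submission], schema: SubmissionSchema | None = None
    ) -> "RegionalReference":
        """Fallback reference: the mean of each metric over a cohort."""
        schema = schema or default_schema()
        pools: dict[str, list[float]] = {k: [] for k in (
            "m_daily", "bed_infusion", "groups_per_syringe",
            "unreasonable_rate", "disposition_rate", "error_rate")}
        for sub in subs:
            m = derive_metrics(sub, schema)
            for key in pools:
                v = getattr(m, key)
                if is_defined(v):
                    pools[key].append(float(v))
        def mean(key: str) -> float:
            vals = pools[key]
            if not vals:
                raise ValueError(f"cannot derive reference {key}: no defined values in cohort")
            return sum(vals) / len(vals)
        return cls(
            avg_daily_deployment=mean("m_daily"),
            avg_bed_infusion=mean("bed_infusion"),
            avg_groups_per_syringe=mean("groups_per_syringe"),
            avg_unreasonable_rate=mean("unreasonable_rate"),
            avg_disposition_rate=mean("disposition_rate"),
            avg_error_rate=mean("error_rate"),
            provenance="cohort-derived",
        )

    def to_dict(self) -> dict[str, Any]:
        return {
            "avg_daily_deployment": self.avg_daily_deployment,
            "avg_bed_infusion": self.avg_bed_infusion,
            "avg_groups_per_syringe": self.avg_groups_per_syringe,
            "avg_unreasonable_rate": self.avg_unreasonable_rate,
            "avg_disposition_rate": self.avg_disposition_rate,
            "avg_error_rate": self.avg_error_rate,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RegionalReference":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__ if k in d})


# ---------------------------------------------------------------------------
# indicators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoringContext:
    metrics: DerivedMetrics
    sub: Submission
    refs: RegionalReference
    schema: SubmissionSchema

    def metric(self, name: str) -> Any:
        v = getattr(self.metrics, name)
        if not is_defined(v):
            raise _UndefinedInput([name])
        return v

    def item(self, item_id: str) -> Any:
        v = self.sub.get(item_id)
        if v is None:
            raise _UndefinedInput([item_id])
        return v


Scorer = Callable[[ScoringContext, Mapping[str, Any]], tuple[float, str]]


@dataclass(frozen=True)
class IndicatorSpec:
    """One row of the evaluation matrix."""

    id: str
    name: str
    category: str
    max_points: float
    inputs: tuple[str, ...]
    scorer: Scorer
    params: Mapping[str, Any] = field(default_factory=dict)

    def score(self, ctx: ScoringContext) -> tuple[float, str]:
        points, branch = self.scorer(ctx, self.params)
        if not (0 <= points <= self.max_points):
            raise AssertionError(
                f"{self.id}: branch {branch} yielded {points} outside [0, {self.max_points}]"
            )
        return points, branch


@dataclass(frozen=True)
class IndicatorScore:
    indicator_id: str
    points: float
    max_points: float
    branch_id: str
    undefined_inputs: tuple[str, ...] = ()


@dataclass(frozen=True)
class RubricSpec:
    version: str
    indicators: tuple[IndicatorSpec, ...]

    def __post_init__(self) -> None:
        ids = [i.id for i in self.indicators]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate indicator ids")

    def __getitem__(self, indicator_id: str) -> IndicatorSpec:
        for ind in self.indicators:
            if ind.id == indicator_id:
                return ind
        raise KeyError(indicator_id)

    def by_category(self, category: str) -> list[IndicatorSpec]:
        return [i for i in self.indicators if i.category == category]


@dataclass
class ScoreCard:
    """Scores for one submission: 20 indicators, 5 category subtotals, total."""

    facility_id: str
    period: Any
    rubric_version: str
    indicators: dict[str, IndicatorScore]
    annotations: list[str] = field(default_factory=list)

    @property
    def category_subtotals(self) -> dict[str, float]:
        out = {c: 0.0 for c in CATEGORIES}
        for ind_id, sc in self.indicators.items():
            out[_CATEGORY_OF[ind_id]] += sc.points
        return out

    @property
    def total(self) -> float:
        return sum(sc.points for sc in self.indicators.values())

    def to_dict(self) -> dict[str, Any]:
        return {
            "facility_id": self.facility_id,
            "period": str(self.period),
            "rubric_version": self.rubric_version,
            "indicators": {
                k: {
                    "points": v.points,
                    "max_points": v.max_points,
                    "branch_id": v.branch_id,
                    "undefined_inputs": list(v.undefined_inputs),
                }
                for k, v in self.indicators.items()
            },
            "category_subtotals": self.category_subtotals,
            "total": self.total,
            "annotations": list(self.annotations),
        }


# -- branch tables ----------------------------------------------------------

def required_working_area(m_daily: float, p: Mapping[str, Any]) -> float:
    """Minimum working area (m²) for a given average daily deployment."""
    if m_daily <= 1000:
        return 300.0
    if m_daily <= 2000:
        return 300.0  # guidance band is 300-500; the floor is the requirement
    if m_daily <= 3000:
        return 500.0
    return 650.0 + 50.0 * math.ceil((m_daily - 3000) / 500.0)


def _score_working_area(ctx: ScoringContext, p: Mapping[str, Any]) -> tuple[float, str]:
    m = ctx.metric("m_daily")
    area = ctx.item("B01")
    req = required_working_area(m, p)
    return (p["points"], "meets") if area >= req else (0.0, "below-minimum")


def _score_auxiliary_area(ctx: ScoringContext, p: Mapping[str, Any]) -> tuple[float, str]:
    return (p["points"], "present") if ctx.item("B09") > 0 else (0.0, "absent")


def _score_consoles(ctx: ScoringContext, p: Mapping[str, Any]) -> tuple[float, str]:
    consoles = ctx.metric("consoles")
    beds = ctx.item("B10")
    need = math.ceil(beds / p["beds_per_console"])
    return (p["points"], "meets") if consoles >= need else (0.0, "short")


def _score_training(ctx: ScoringContext, p: Mapping[str, Any]) -> tuple[float, str]:
    r = ctx.metric("training_ratio")
    if r > p["hi"]:
        return p["pts_hi"], "gt1"
    if r >= p["lo"]:
        return p["pts_mid"], "0.2to1"
    return 0.0, "lt0.2"


def _score_personnel_types(ctx: ScoringContext, p: Mapping[str, Any]) -> tuple[float, str]:
    prop = ctx.metric("pharmacist_prop")
    if prop == 1:
        return p["pts_all"], "all-pharmacists"
    if prop >= 0.5:
        return p["pts_majority"], "majority-pharmacists"
    if prop > 0:
        return p["pts_minority"], "majority-nurses"
    return 0.0, "all-nurses"


def _score_director(ctx: ScoringContext, p: Mapping[str, Any]) -> tuple[float, str]:
    title = ctx.item("C09")
    degree = ctx.item("C05")
    titles = ctx.schema.vocabularies["director_title"]
    degrees = ctx.schema.vocabularies["degree"]
    ok = titles.at_or_above_threshold(title) and degrees.at_or_above_threshold(degree)
    return (p["pts_qualified"], "qualified") if ok else (p["pts_unqualified"], "unqualified")


#: drug classes: (item, short tag, points) — additive
_INFUSION_CLASSES = (("D12", "pn", 3.0), ("D03", "ac", 3.0), ("D02", "ab", 2.0), ("D11", "gd", 2.0))


def _score_infusion_types(ctx: ScoringContext, p: Mapping[str, Any]) -> tuple[float, str]:
    points = 0.0
    tags = []
    for item_id, tag, pts in _INFUSION_CLASSES:
        if ctx.item(item_id) > 0:
            points += pts
            tags.append(tag)
    return points, "classes:" + ("+".join(tags) if tags else "none")


def _score_daily_deployment(ctx: ScoringContext, p: Mapping[str, Any]) -> tuple[float, str]:
    m = ctx.metric("m_daily")
    a = ctx.refs.avg_daily_deployment
    if m > a:
        return p["pts"][0], "above-avg"
    if m > (2.0 / 3.0) * a:
        return p["pts"][1], "two-thirds-to-avg"
    if m > (1.0 / 3.0) * a:
        return p["pts"][2], "one-third-to-two-thirds"
    return p["pts"][3], "below-one-third"


def _score_bed_infusion(ctx: ScoringContext, p: Mapping[str, Any]) -> tuple[float, str]:
    q = ctx.metric("bed_infusion")
    return (p["pts_lo"], "below-avg") if q < ctx.refs.avg_bed_infusion else (p["pts_hi"], "above-avg")


def _score_syringe(ctx: ScoringContext, p: Mapping[str, Any]) -> tuple[float, str]:
    g = ctx.metric("groups_per_syringe")
    return (p["pts_lo"], "below-avg") if g < ctx.refs.avg_groups_per_syringe else (p["pts_hi"], "above-avg")


def _score_allocation(ctx: ScoringContext, p: Mapping[str, Any]) -> tuple[float, str]:
    d13 = ctx.item("D13")
    return (p["points"], "below-100") if d13 < p["limit"] else (0.0, "at-or-above-100")


def _score_temporary_rate(ctx: ScoringContext, p: Mapping[str, Any]) -> tuple[float, str]:
    r = ctx.metric("temp_rate")
    if r > p["hi"]:
        return p["pts_hi"], "above-5pct"
    if r >= p["lo"]:
        return p["pts_mid"], "3-5pct"
    return 0.0, "below-3pct"


def _score_reviewed(ctx: ScoringContext, p: Mapping[str, Any]) -> tuple[float, str]:
    d04 = ctx.item("D04")
    if d04 < p["lo"]:
        return p["pts"][0], "below-500"
    if d04 <= p["hi"]:
        return p["pts"][1], "500-800"
    return p["pts"][2], "above-800"


def _score_unreasonable(ctx: ScoringContext, p: Mapping[str, Any]) -> tuple[float, str]:
    rate = ctx.metric("unreasonable_rate")
    disp = ctx.metric("disposition_rate")
    rate_lo = rate < ctx.refs.avg_unreasonable_rate
    disp_hi = disp > ctx.refs.avg_disposition_rate
    disp_ge = disp >= ctx.refs.avg_disposition_rate
    if rate_lo and disp_hi:
        return p["pts"][0], "rate-lo-disp-hi"
    if not rate_lo and disp_ge:
        return p["pts"][1], "rate-hi-disp-hi"
    if rate_lo:
        return p["pts"][2], "rate-lo-disp-lo"
    return p["pts"][3], "rate-hi-disp-lo"


def _score_error_control(ctx: ScoringContext, p: Mapping[str, Any]) -> tuple[float, str]:
    e = ctx.metric("error_rate")
    a = ctx.refs.avg_error_rate
    if e < a:
        return p["pts"][0], "below-avg"
    if e <= p["excess"] * a:
        return p["pts"][1], "avg-to-1.3avg"
    return p["pts"][2], "above-1.3avg"


def _score_cleaning(ctx: ScoringContext, p: Mapping[str, Any]) -> tuple[float, str]:
    rate = ctx.item("E01") / ctx.sub.period.weeks  # cleanings per week
    if rate >= 1.0:
        return p["pts"][0], "weekly"
    if rate >= 0.5:
        return p["pts"][1], "biweekly"
    if rate >= 12.0 / 52.0:
        return p["pts"][2], "monthly"
    return 0.0, "rarer"


def _score_air_filters(ctx: ScoringContext, p: Mapping[str, Any]) -> tuple[float, str]:
    k = sum(1 for item in ("E04", "E05", "E06") if ctx.item(item) > 0)
    if k == 3:
        return p["pts"][0], "all-three"
    if k >= 1:
        return p["pts"][1], "one-or-two"
    return 0.0, "none"


def _score_disinfection(ctx: ScoringContext, p: Mapping[str, Any]) -> tuple[float, str]:
    n = ctx.metric("disinfection_methods")
    return (p["points"], "two-plus") if n >= 2 else (0.0, "single")


def _score_informatics(ctx: ScoringContext, p: Mapping[str, Any]) -> tuple[float, str]:
    points = 0.0
    tags = []
    if ctx.item("F02"):
        points += p["pts_info_system"]
        tags.append("is")
    if ctx.item("F03"):
        points += p["pts_clinical_system"]
        tags.append("crs")
    eq = min(p["equipment_cap"], ctx.metric("equipment_count"))
    points += eq
    tags.append(f"eq{int(eq)}")
    return points, "+".join(tags)


def _score_tracing(ctx: ScoringContext, p: Mapping[str, Any]) -> tuple[float, str]:
    consoles = ctx.metric("consoles")
    if consoles == 0:
        raise _UndefinedInput(["consoles"])
    ratio = ctx.metric("traceable_count") / consoles
    return classify_tracing(ratio, p)


def classify_tracing(ratio: float, p: Mapping[str, Any] | None = None) -> tuple[float, str]:
    p = p or {"pts": (5.0, 3.0, 2.0, 1.0)}
    if ratio > 2:
        return p["pts"][0], "above-2"
    if ratio > 1:
        return p["pts"][1], "1-2"
    if ratio > 0.5:
        return p["pts"][2], "0.5-1"
    if ratio > 0.1:
        return p["pts"][3], "0.1-0.5"
    return 0.0, "at-most-0.1"


def default_rubric() -> RubricSpec:
    """The shipped evaluation matrix (20 indicators, total max 100)."""
    I = IndicatorSpec
    indicators = (
        I("H1", "rationality of working area", HARDWARE, 5, ("B01", "m_daily"),
          _score_working_area, {"points": 5.0}),
        I("H2", "auxiliary functional area", HARDWARE, 1, ("B09",),
          _score_auxiliary_area, {"points": 1.0}),
        I("H3", "workbench quantity for served beds", HARDWARE, 5, ("consoles", "B10"),
          _score_consoles, {"points": 5.0, "beds_per_console": 100}),
        I("P1", "staff training", PERSONNEL, 5, ("training_ratio",),
          _score_training, {"hi": 1.0, "lo": 0.2, "pts_hi": 5.0, "pts_mid": 2.0}),
        I("P2", "personnel types", PERSONNEL, 5, ("pharmacist_prop",),
          _score_personnel_types, {"pts_all": 5.0, "pts_majority": 4.0, "pts_minority": 2.0}),
        I("P3", "director qualification", PERSONNEL, 4, ("C09", "C05"),
          _score_director, {"pts_qualified": 4.0, "pts_unqualified": 2.0}),
        I("W1", "types of infusion dispensed", WORK_EFFICIENCY, 10, ("D02", "D03", "D11", "D12"),
          _score_infusion_types, {}),
        I("W2", "average daily deployment", WORK_EFFICIENCY, 5, ("m_daily", "avg_daily_deployment"),
          _score_daily_deployment, {"pts": (5.0, 4.0, 3.0, 2.0)}),
        I("W3", "daily bed infusion quantity", WORK_EFFICIENCY, 3, ("bed_infusion", "avg_bed_infusion"),
          _score_bed_infusion, {"pts_lo": 3.0, "pts_hi": 1.0}),
        I("W4", "usage of syringes", WORK_EFFICIENCY, 5, ("groups_per_syringe", "avg_groups_per_syringe"),
          _score_syringe, {"pts_lo": 5.0, "pts_hi": 4.0}),
        I("W5", "daily allocation per person", WORK_EFFICIENCY, 5, ("D13",),
          _score_allocation, {"points": 5.0, "limit": 100}),
        I("W6", "temporary-order deployment rate", WORK_EFFICIENCY, 5, ("temp_rate",),
          _score_temporary_rate, {"hi": 0.05, "lo": 0.03, "pts_hi": 5.0, "pts_mid": 3.0}),
        I("W7", "daily prescriptions reviewed per person", WORK_EFFICIENCY, 6, ("D04",),
          _score_reviewed, {"lo": 500, "hi": 800, "pts": (6.0, 3.0, 0.0)}),
        I("W8", "unreasonable prescriptions and disposition", WORK_EFFICIENCY, 5,
          ("unreasonable_rate", "disposition_rate", "avg_unreasonable_rate", "avg_disposition_rate"),
          _score_unreasonable, {"pts": (5.0, 3.0, 3.0, 1.0)}),
        I("W9", "error control rate", WORK_EFFICIENCY, 5, ("error_rate", "avg_error_rate"),
          _score_error_control, {"pts": (5.0, 3.0, 2.0), "excess": 1.3}),
        I("I1", "comprehensive cleaning frequency", INFECTION_CONTROL, 5, ("E01",),
          _score_cleaning, {"pts": (5.0, 3.0, 1.0)}),
        I("I2", "air-filter cleaning and maintenance", INFECTION_CONTROL, 5, ("E04", "E05", "E06"),
          _score_air_filters, {"pts": (5.0, 3.0)}),
        I("I3", "disinfection methods", INFECTION_CONTROL, 3, ("disinfection_methods",),
          _score_disinfection, {"points": 3.0}),
        I("N1", "degree of informatics", INFORMATION, 8, ("F02", "F03", "equipment_count"),
          _score_informatics, {"pts_info_system": 3.0, "pts_clinical_system": 2.0, "equipment_cap": 3}),
        I("N2", "tracing control", INFORMATION, 5, ("traceable_count", "consoles"),
          _score_tracing, {"pts": (5.0, 3.0, 2.0, 1.0)}),
    )
    return RubricSpec(version=RUBRIC_VERSION, indicators=indicators)


_CATEGORY_OF = {i.id: i.category for i in default_rubric().indicators}


def rubric_maxima(rubric: RubricSpec | None = None) -> dict[str, float]:
    """Per-indicator, per-category and total maxima of a rubric."""
    rubric = rubric or default_rubric()
    out: dict[str, float] = {}
    for ind in rubric.indicators:
        out[ind.id] = ind.max_points
    for cat in CATEGORIES:
        out[cat] = sum(i.max_points for i in rubric.by_category(cat))
    out["total"] = sum(i.max_points for i in rubric.indicators)
    return out


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score_indicator(
    metrics: DerivedMetrics,
    sub: Submission,
    spec: IndicatorSpec,
    refs: RegionalReference,
    schema: SubmissionSchema | None = None,
    policy: str = "lenient",
) -> IndicatorScore:
    """Score one indicator; the first matching branch fires.

    Under ``policy="strict"`` an undefined input raises :class:`ScoringError`
    naming the indicator; under ``"lenient"`` the indicator scores 0 with
    the offending inputs recorded.
    """
    schema = schema or default_schema()
    ctx = ScoringContext(metrics=metrics, sub=sub, refs=refs, schema=schema)
    try:
        points, branch = spec.score(ctx)
    except _UndefinedInput as exc:
        if policy == "strict":
            raise ScoringError(
                f"indicator {spec.id} ({spec.name}): undefined inputs {exc.names}"
            ) from None
        return IndicatorScore(spec.id, 0.0, spec.max_points, "undefined-input",
                              undefined_inputs=tuple(exc.names))
    return IndicatorScore(spec.id, points, spec.max_points, branch)


def score_submission(
    sub: Submission,
    rubric: RubricSpec | None = None,
    refs: RegionalReference | None = None,
    schema: SubmissionSchema | None = None,
    policy: str = "lenient",
) -> ScoreCard:
    """Score a submission on all 20 indicators and assemble a ScoreCard."""
    rubric = rubric or default_rubric()
    schema = schema or default_schema()
    if refs is None:
        refs = RegionalReference.from_cohort([sub], schema)
    metrics = derive_metrics(sub, schema)

    scores: dict[str, IndicatorScore] = {}
    annotations: list[str] = []
    failures: list[str] = []
    for spec in rubric.indicators:
        try:
            sc = score_indicator(metrics, sub, spec, refs, schema, policy=policy)
        except ScoringError as exc:
            failures.append(str(exc))
            continue
        scores[spec.id] = sc
        if sc.branch_id == "undefined-input":
            annotations.append(
                f"{spec.id}: scored 0, undefined inputs {list(sc.undefined_inputs)}"
            )
    if failures:
        raise ScoringError("; ".join(failures))
    return ScoreCard(
        facility_id=sub.facility_id,
        period=sub.period,
        rubric_version=rubric.version,
        indicators=scores,
        annotations=annotations,
    )


def scorecard_from_dict(d: Mapping[str, Any]) -> ScoreCard:
    """Inverse of :meth:`ScoreCard.to_dict` (period round-trips as text)."""
    from .schema import Period

    indicators = {
        k: IndicatorScore(
            indicator_id=k,
            points=float(v["points"]),
            max_points=float(v["max_points"]),
            branch_id=v["branch_id"],
            undefined_inputs=tuple(v.get("undefined_inputs", ())),
        )
        for k, v in d["indicators"].items()
    }
    return ScoreCard(
        facility_id=d["facility_id"],
        period=Period.parse(d["period"]),
        rubric_version=d["rubric_version"],
        indicators=indicators,
        annotations=list(d.get("annotations", [])),
    )


# ---------------------------------------------------------------------------
# config round-trip (parameters only; branch logic is versioned code)
# ---------------------------------------------------------------------------

def rubric_to_config(rubric: RubricSpec | None = None) -> dict[str, Any]:
    rubric = rubric or default_rubric()
    return {
        "version": rubric.version,
        "indicators": {
            i.id: {
                "name": i.name,
                "category": i.category,
                "max_points": i.max_points,
                "params": {k: list(v) if isinstance(v, tuple) else v for k, v in i.params.items()},
            }
            for i in rubric.indicators
        },
    }


def rubric_from_config(config: Mapping[str, Any]) -> RubricSpec:
    """Rebuild a rubric from a config document, overriding default params."""
    base = default_rubric()
    overrides = config.get("indicators", {})
    indicators = []
    for ind in base.indicators:
        ov = overrides.get(ind.id, {})
        params = dict(ind.params)
        for k, v in ov.get("params", {}).items():
            params[k] = tuple(v) if isinstance(v, list) else v
        indicators.append(replace(ind, params=params, max_points=ov.get("max_points", ind.max_points)))
    return RubricSpec(version=config.get("version", base.version), indicators=tuple(indicators))
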