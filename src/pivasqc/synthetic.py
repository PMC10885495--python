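"""Seeded synthetic facility cohorts.

Generation is *branch-first*: a latent quality in [0, 1] per facility-year
is mapped monotonically to a target branch of every indicator, and the raw
data items are then back-solved so the submission lands on that branch.
This guarantees every rubric branch is reachable in tests, that every
generated submission passes audit, and that the generator's intent (the
``truth`` sidecar) can be checked against the scoring engine.

All randomness flows through one ``numpy`` generator seeded from the
config, so identical configs produce byte-identical panels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import stats

from .rubric import (
    RegionalReference,
    RubricSpec,
    classify_tracing,
    default_rubric,
    required_working_area,
    score_submission,
)
from .schema import (
    Period,
    Submission,
    SubmissionSchema,
    aggregate_year,
    audit_submission,
    default_schema,
)

__all__ = [
    "CohortConfig",
    "FacilityYearTruth",
    "SyntheticPanel",
    "RecoveryReport",
    "default_reference_anchors",
    "generate_cohort",
    "recover_quality",
]

_DAYS_PER_QUARTER = 91.0


def default_reference_anchors() -> RegionalReference:
    """Reference averages the synthetic world is closed under."""
    return RegionalReference(
        avg_daily_deployment=1500.0,     # bags/day
        avg_bed_infusion=3.0,            # bags/bed/day
        avg_groups_per_syringe=3.0,
        avg_unreasonable_rate=2.0,       # percent
        avg_disposition_rate=0.70,
        avg_error_rate=0.002,
        provenance="configured",
    )


@dataclass(frozen=True)
class CohortConfig:
    """Knobs of the cohort generator.

    ``quality_*`` parameterize the latent facility quality on a 0-1 scale;
    ``drift`` is added per elapsed year and ``noise`` is the SD of the
    per-indicator jitter applied before branch selection. With ``clamp``
    disabled, a latent quality leaving [0, 1] is an error instead of being
    clipped.
    """

    n_facilities: int = 15
    start_year: int = 2020
    years: int = 3
    quarters_per_year: int = 4
    quality_mean: float = 0.55
    quality_sd: float = 0.18
    drift: float = 0.10
    noise: float = 0.0
    bed_range: tuple[int, int] = (500, 900)
    refs: RegionalReference = field(default_factory=default_reference_anchors)
    clamp: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_facilities < 1 or self.years < 1 or not 1 <= self.quarters_per_year <= 4:
            raise ValueError("invalid cohort dimensions")
        if self.bed_range[0] < 200 or self.bed_range[1] > 1000 or self.bed_range[0] > self.bed_range[1]:
            raise ValueError("bed_range must lie within [200, 1000]")


@dataclass
class FacilityYearTruth:
    facility_id: str
    year: int
    latent_quality: float
    branches: dict[str, str]   # indicator id -> generated branch id
    points: dict[str, float]   # indicator id -> generated points

    @property
    def total(self) -> float:
        return sum(self.points.values())

    def to_dict(self) -> dict[str, Any]:
        return {
            "facility_id": self.facility_id,
            "year": self.year,
            "latent_quality": self.latent_quality,
            "branches": dict(self.branches),
            "points": dict(self.points),
        }


@dataclass
class SyntheticPanel:
    config: CohortConfig
    submissions: list[Submission]
    truth: list[FacilityYearTruth]
    refs: RegionalReference

    def yearly_submissions(self, schema: SubmissionSchema | None = None) -> list[Submission]:
        """Annual roll-ups, one per facility-year, in truth order."""
        schema = schema or default_schema()
        by_key: dict[tuple[str, int], list[Submission]] = {}
        for sub in self.submissions:
            by_key.setdefault((sub.facility_id, sub.period.year), []).append(sub)
        return [aggregate_year(by_key[(t.facility_id, t.year)], schema) for t in self.truth]


def _clamp01(x: float) -> float:
    return min(1.0, max(0.0, x))


def _pick(q: float, n_rungs: int) -> int:
    """Monotone map from quality to a rung index (0 = best rung)."""
    return min(n_rungs - 1, max(0, int((1.0 - q) * n_rungs)))


def _jitter(rng: np.random.Generator, lo: float = 0.96, hi: float = 1.04) -> float:
    return float(rng.uniform(lo, hi))


class _Builder:
    """Accumulates the 67 items plus the truth records for one facility-year."""

    def __init__(self, rng: np.random.Generator, refs: RegionalReference, noise: float, q: float):
        self.rng = rng
        self.refs = refs
        self.noise = noise
        self.q = q
        self.items: dict[str, Any] = {}
        self.branches: dict[str, str] = {}
        self.points: dict[str, float] = {}

    def q_eff(self) -> float:
        # one jitter draw per indicator keeps the rng stream deterministic
        return _clamp01(self.q + self.noise * float(self.rng.normal()))

    def hit(self, ind: str, branch: str, points: float) -> None:
        self.branches[ind] = branch
        self.points[ind] = points


def _gen_basic_info(b: _Builder, facility_id: str, grade: str, start_year: int) -> None:
    i = b.items
    num = facility_id.split("-")[-1]
    i["A01"] = f"Hospital {num}"
    i["A02"] = f"{num} Main Street"
    i["A03"] = f"Rep {num}"
    i["A04"] = f"Pharmacy Director {num}"
    i["A05"] = 87100000 + int(num)
    i["A06"] = f"Reporter {num}"
    i["A07"] = "pharmacist in charge"
    i["A08"] = grade
    i["A09"] = 650000 + int(num)
    i["A10"] = f"Institution Director {num}"
    i["A11"] = 13800000000 + int(num)
    i["A12"] = f"{start_year - 5}-01-01"


def _gen_hardware(b: _Builder, beds_total: int, beds_pivas: int) -> None:
    """H2/H3 plus the unscored hardware fillers. H1 needs m_daily, done later."""
    rng, i = b.rng, b.items
    i["B02"] = beds_total
    i["B03"] = beds_total // 40 + 1
    i["B04"] = beds_pivas // 2
    i["B10"] = beds_pivas
    i["B11"] = beds_pivas
    i["B06"] = int(rng.integers(2, 7))
    i["B07"] = int(rng.integers(2, 7))

    # H2: auxiliary (rest) area
    if _pick(b.q_eff(), 2) == 0:
        i["B09"] = round(float(rng.uniform(20, 60)), 1)
        b.hit("H2", "present", 1.0)
    else:
        i["B09"] = 0.0
        b.hit("H2", "absent", 0.0)

    # H3: consoles per 100 served beds; bed_range >= 200 keeps need >= 2, so
    # the failing rung still leaves at least one console for tracing control
    need = math.ceil(beds_pivas / 100)
    if _pick(b.q_eff(), 2) == 0:
        total = need
        b.hit("H3", "meets", 5.0)
    else:
        total = need - 1
        b.hit("H3", "short", 0.0)
    i["B05"] = total // 3
    i["B08"] = total // 3
    i["B12"] = total - 2 * (total // 3)


def _gen_personnel(b: _Builder, beds_pivas: int, schema: SubmissionSchema) -> None:
    rng, i = b.rng, b.items
    staff = max(4, round(beds_pivas / 40))

    # P2: pharmacist share of pharmacist+nurse staff
    rung = _pick(b.q_eff(), 4)
    if rung == 0:
        c10 = staff
        b.hit("P2", "all-pharmacists", 5.0)
    elif rung == 1:
        c10 = max(staff // 2 + 1, round(0.65 * staff))
        b.hit("P2", "majority-pharmacists", 4.0)
    elif rung == 2:
        c10 = max(1, round(0.3 * staff))
        b.hit("P2", "majority-nurses", 2.0)
    else:
        c10 = 0
        b.hit("P2", "all-nurses", 0.0)
    i["C10"] = c10
    i["C06"] = staff - c10
    i["C01"] = int(rng.integers(1, 4))
    i["C04"] = beds_pivas

    # P1: training sessions per trained person
    c03 = max(1, round(0.6 * staff))
    c08 = max(1, round(0.8 * staff))
    i["C03"], i["C08"] = c03, c08
    trainers = c03 + c08
    rung = _pick(b.q_eff(), 3)
    if rung == 0:
        sessions = trainers + max(1, trainers // 3)
        b.hit("P1", "gt1", 5.0)
    elif rung == 1:
        sessions = max(1, round(0.6 * trainers))
        b.hit("P1", "0.2to1", 2.0)
    else:
        sessions = 0
        b.hit("P1", "lt0.2", 0.0)
    i["C02"] = sessions // 2
    i["C07"] = sessions - sessions // 2

    # P3: director title and degree
    titles = schema.vocabularies["director_title"].ordered_levels
    degrees = schema.vocabularies["degree"].ordered_levels
    if _pick(b.q_eff(), 2) == 0:
        i["C09"] = titles[2 + int(rng.integers(0, 3))]   # supervising or above
        i["C05"] = degrees[2 + int(rng.integers(0, 3))]  # bachelor or above
        b.hit("P3", "qualified", 4.0)
    else:
        i["C09"] = titles[int(rng.integers(0, 2))]
        i["C05"] = degrees[int(rng.integers(0, 2))]
        b.hit("P3", "unqualified", 2.0)


#: best-to-worst rungs for the additive infusion-class indicator
_W1_RUNGS = (
    (("pn", "ac", "ab", "gd"), 10.0),
    (("pn", "ac", "gd"), 8.0),
    (("pn", "gd"), 5.0),
    (("gd",), 2.0),
)
_CLASS_ITEM = {"pn": "D12", "ac": "D03", "ab": "D02", "gd": "D11"}
_CLASS_WEIGHT = {"pn": 0.10, "ac": 0.15, "ab": 0.25, "gd": 0.50}
_CLASS_ORDER = ("pn", "ac", "ab", "gd")  # scorer tag order


def _gen_work_efficiency(b: _Builder, beds_pivas: int) -> None:
    rng, i, refs = b.rng, b.items, b.refs
    A = refs.avg_daily_deployment

    # W2 x W6 are coupled through D05/D15; pick both targets then back-solve
    w2_mults = (1.25, 0.85, 0.50, 0.25)
    w2_branches = ("above-avg", "two-thirds-to-avg", "one-third-to-two-thirds", "below-one-third")
    w2_pts = (5.0, 4.0, 3.0, 2.0)
    r2 = _pick(b.q_eff(), 4)
    m_target = A * w2_mults[r2] * _jitter(rng)

    w6_rates = (0.08, 0.04, 0.015)
    w6_branches = ("above-5pct", "3-5pct", "below-3pct")
    w6_pts = (5.0, 3.0, 0.0)
    r6 = _pick(b.q_eff(), 3)
    t_target = w6_rates[r6] * _jitter(rng, 0.92, 1.08)

    d05 = max(1, round(m_target / (1.0 + t_target)))
    d15 = max(1, round(d05 * t_target))
    i["D05"], i["D15"] = d05, d15
    b.hit("W2", w2_branches[r2], w2_pts[r2])
    b.hit("W6", w6_branches[r6], w6_pts[r6])
    m_daily = d05 + d15
    d01 = round(m_daily * _DAYS_PER_QUARTER)
    i["D01"] = d01

    # W1: which drug classes are dispensed (additive points)
    rung, pts = _W1_RUNGS[_pick(b.q_eff(), 4)]
    weights = {c: _CLASS_WEIGHT[c] for c in rung}
    wsum = sum(weights.values())
    remaining = d01
    for idx, c in enumerate(_CLASS_ORDER):
        item = _CLASS_ITEM[c]
        if c not in rung:
            i[item] = 0
            continue
        if idx == max(_CLASS_ORDER.index(x) for x in rung):
            amount = remaining
        else:
            amount = max(1, round(d01 * weights[c] / wsum))
        i[item] = amount
        remaining -= amount
    tags = [c for c in _CLASS_ORDER if c in rung]
    b.hit("W1", "classes:" + "+".join(tags), pts)

    # W3: bed infusion quantity per day
    r3 = _pick(b.q_eff(), 2)
    ratio = refs.avg_bed_infusion * (0.75 if r3 == 0 else 1.30) * _jitter(rng)
    i["D10"] = round(ratio * beds_pivas * _DAYS_PER_QUARTER)
    b.hit("W3", "below-avg" if r3 == 0 else "above-avg", 3.0 if r3 == 0 else 1.0)

    # W4: infusion groups per syringe
    r4 = _pick(b.q_eff(), 2)
    g_target = refs.avg_groups_per_syringe * (0.75 if r4 == 0 else 1.30) * _jitter(rng)
    i["D09"] = max(1, round(d01 / g_target))
    b.hit("W4", "below-avg" if r4 == 0 else "above-avg", 5.0 if r4 == 0 else 4.0)

    # W5: daily allocation per person
    if _pick(b.q_eff(), 2) == 0:
        i["D13"] = int(rng.integers(80, 96))
        b.hit("W5", "below-100", 5.0)
    else:
        i["D13"] = int(rng.integers(105, 140))
        b.hit("W5", "at-or-above-100", 0.0)

    # W7: prescriptions reviewed per person per day
    r7 = _pick(b.q_eff(), 3)
    i["D04"] = int((rng.integers(250, 450), rng.integers(550, 750), rng.integers(820, 980))[r7])
    b.hit("W7", ("below-500", "500-800", "above-800")[r7], (6.0, 3.0, 0.0)[r7])

    # W8: unreasonable-prescription rate (vs avg, percent) x disposition rate
    d14 = round(d01 * 0.5)
    i["D14"] = d14
    r8 = _pick(b.q_eff(), 4)
    rate_mult = (0.6, 1.4, 0.6, 1.4)[r8]
    disp_delta = (0.15, 0.12, -0.20, -0.20)[r8]
    rate = refs.avg_unreasonable_rate * rate_mult * _jitter(rng)
    disp = min(0.95, max(0.05, refs.avg_disposition_rate + disp_delta))
    d06 = max(1, round(rate / 100.0 * d14))
    d17 = min(d06, max(0, round(disp * d06)))
    i["D06"], i["D17"] = d06, d17
    i["D16"] = round(100.0 * d06 / d14, 2)
    i["D07"] = "returning" if r8 in (0, 1) else "packing"
    b.hit("W8", ("rate-lo-disp-hi", "rate-hi-disp-hi", "rate-lo-disp-lo", "rate-hi-disp-lo")[r8],
          (5.0, 3.0, 3.0, 1.0)[r8])

    # W9: preparation errors per dispensed infusion
    r9 = _pick(b.q_eff(), 3)
    e_target = refs.avg_error_rate * (0.6, 1.15, 1.6)[r9] * _jitter(rng, 0.98, 1.02)
    errors = max(0 if r9 == 0 else 1, round(e_target * d01))
    i["D08"] = errors // 3
    i["D18"] = errors // 3
    i["D19"] = errors - 2 * (errors // 3)
    b.hit("W9", ("below-avg", "avg-to-1.3avg", "above-1.3avg")[r9], (5.0, 3.0, 2.0)[r9])


def _gen_infection_control(b: _Builder, schema: SubmissionSchema) -> None:
    rng, i = b.rng, b.items

    # I1: cleanings per quarter -> weekly-equivalent rungs
    r1 = _pick(b.q_eff(), 4)
    i["E01"] = (13, 7, 3, 1)[r1]
    b.hit("I1", ("weekly", "biweekly", "monthly", "rarer")[r1], (5.0, 3.0, 1.0, 0.0)[r1])

    # I2: air-filter kinds maintained during the year
    r2 = _pick(b.q_eff(), 3)
    i["E04"], i["E05"], i["E06"] = ((1, 1, 1), (1, 1, 0), (0, 0, 0))[r2]
    b.hit("I2", ("all-three", "one-or-two", "none")[r2], (5.0, 3.0, 0.0)[r2])

    # I3: number of disinfection methods
    methods = schema.vocabularies["disinfection"].ordered_levels
    if _pick(b.q_eff(), 2) == 0:
        k = 2 + int(rng.integers(0, 2))
        i["E11"] = ", ".join(methods[:k])
        b.hit("I3", "two-plus", 3.0)
    else:
        i["E11"] = methods[int(rng.integers(0, 2))]
        b.hit("I3", "single", 0.0)

    for item, lo, hi in (("E02", 90, 100), ("E03", 92, 100), ("E07", 90, 100), ("E08", 90, 100)):
        i[item] = round(float(rng.uniform(lo, hi)), 1)
    i["E09"] = int(rng.integers(1, 11))
    i["E10"] = int(rng.integers(4, 14))


def _gen_information(b: _Builder, schema: SubmissionSchema) -> None:
    """N1 and N2 share F01, so both are composed before recording truth."""
    rng, i = b.rng, b.items
    vocab = schema.vocabularies["equipment"]
    traceable_kinds = [k for k in vocab.ordered_levels if k in vocab.traceable]
    plain_kinds = [k for k in vocab.ordered_levels if k not in vocab.traceable]
    consoles = i["B05"] + i["B08"] + i["B12"]

    # N2 target: traceability-capable kinds per console
    r2 = _pick(b.q_eff(), 5)
    if r2 == 0:
        tc = 2 * consoles + 1
    elif r2 == 1:
        tc = 2 * consoles
    elif r2 == 2:
        tc = consoles
    elif r2 == 3:
        tc = max(1, consoles // 2)
    else:
        tc = 0
    tc = min(tc, len(traceable_kinds))

    # N1 rung: systems flags plus equipment-kind component
    r1 = _pick(b.q_eff(), 5)
    f02, f03, eq_extra = ((True, True, 3), (True, True, 2), (True, False, 1),
                          (False, True, 0), (False, False, 0))[r1]
    if tc == 0:
        eq_extra = min(eq_extra, len(plain_kinds))  # keep tracing at zero
        kinds = plain_kinds[:eq_extra]
    else:
        kinds = traceable_kinds[:tc] + plain_kinds[: max(0, eq_extra - tc)]
    i["F01"] = ", ".join(kinds) if kinds else "none"
    i["F02"], i["F03"] = f02, f03

    # recompute what was actually composed and record that as truth
    eq_count = len(kinds)
    tc_actual = sum(1 for k in kinds if k in vocab.traceable)
    n1_eq = min(3, eq_count)
    n1_points = 3.0 * f02 + 2.0 * f03 + n1_eq
    tags = [t for t, on in (("is", f02), ("crs", f03)) if on] + [f"eq{n1_eq}"]
    b.hit("N1", "+".join(tags), n1_points)
    n2_points, n2_branch = classify_tracing(tc_actual / consoles)
    b.hit("N2", n2_branch, n2_points)


def _gen_working_area(b: _Builder) -> None:
    """H1 depends on m_daily, so it runs after work efficiency."""
    rng, i = b.rng, b.items
    m_daily = i["D05"] + i["D15"]
    req = required_working_area(m_daily, {})
    if _pick(b.q_eff(), 2) == 0:
        i["B01"] = round(req * _jitter(rng, 1.05, 1.30), 1)
        b.hit("H1", "meets", 5.0)
    else:
        i["B01"] = round(max(50.0, req * _jitter(rng, 0.60, 0.90)), 1)
        b.hit("H1", "below-minimum", 0.0)


def generate_cohort(cfg: CohortConfig, schema: SubmissionSchema | None = None) -> SyntheticPanel:
    """Generate a seeded synthetic panel of facility-quarter submissions.

    Raises ``ValueError`` for infeasible configs (latent quality escaping
    [0, 1] with clamping disabled) and ``AssertionError`` should a generated
    submission ever fail audit.
    """
    schema = schema or default_schema()
    rng = np.random.default_rng(cfg.seed)
    grades = ("second-level A", "third-level", "third-level A")

    submissions: list[Submission] = []
    truth: list[FacilityYearTruth] = []
    for f in range(cfg.n_facilities):
        facility_id = f"PIVAS-{f + 1:02d}"
        grade = grades[int(rng.integers(0, len(grades)))]
        beds_total = int(rng.integers(cfg.bed_range[0], cfg.bed_range[1] + 1))
        # keep served beds in [150, 800] so console needs stay back-solvable
        beds_pivas = int(min(800, max(150, round(beds_total * rng.uniform(0.45, 0.85)))))
        q_base = float(rng.normal(cfg.quality_mean, cfg.quality_sd))

        for y in range(cfg.years):
            year = cfg.start_year + y
            q = q_base + cfg.drift * y
            if not 0.0 <= q <= 1.0:
                if not cfg.clamp:
                    raise ValueError(
                        f"latent quality {q:.3f} outside [0, 1] for {facility_id} year {year} "
                        "and clamping is disabled"
                    )
                q = _clamp01(q)

            b = _Builder(rng, cfg.refs, cfg.noise, q)
            _gen_basic_info(b, facility_id, grade, cfg.start_year)
            _gen_hardware(b, beds_total, beds_pivas)
            _gen_personnel(b, beds_pivas, schema)
            _gen_work_efficiency(b, beds_pivas)
            _gen_infection_control(b, schema)
            _gen_information(b, schema)
            _gen_working_area(b)

            for quarter in range(1, cfg.quarters_per_year + 1):
                sub = Submission(facility_id=facility_id, period=Period(year, quarter),
                                 items=dict(b.items))
                report = audit_submission(sub, schema=schema)
                if not report.passed:
                    raise AssertionError(
                        f"generated submission failed audit: {report.errors()}"
                    )
                submissions.append(sub)
            truth.append(FacilityYearTruth(facility_id, year, q, b.branches, b.points))
    return SyntheticPanel(config=cfg, submissions=submissions, truth=truth, refs=cfg.refs)


# ---------------------------------------------------------------------------
# recovery
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    spearman_rho: float
    spearman_p: float
    per_year_rho: dict[int, float]
    branch_agreement: float          # fraction of indicator cells matching truth
    points_agreement: float
    n: int

    def to_dict(self) -> dict[str, Any]:
        return {
            "spearman_rho": self.spearman_rho,
            "spearman_p": self.spearman_p,
            "per_year_rho": {str(k): v for k, v in self.per_year_rho.items()},
            "branch_agreement": self.branch_agreement,
            "points_agreement": self.points_agreement,
            "n": self.n,
        }


def recover_quality(
    panel: SyntheticPanel,
    rubric: RubricSpec | None = None,
    refs: RegionalReference | None = None,
    schema: SubmissionSchema | None = None,
) -> RecoveryReport:
    """Score the panel's annual roll-ups and compare against the truth sidecar.

    Reports the Spearman correlation between latent quality and scored
    totals (overall and per year) and the per-indicator agreement between
    the generated branch/points and what the scoring engine reproduces.
    """
    rubric = rubric or default_rubric()
    refs = refs or panel.refs
    schema = schema or default_schema()
    yearly = panel.yearly_submissions(schema)
    cards = [score_submission(s, rubric, refs, schema) for s in yearly]

    latents = np.array([t.latent_quality for t in panel.truth])
    totals = np.array([c.total for c in cards])
    if np.ptp(latents) == 0 or np.ptp(totals) == 0:
        rho, p = float("nan"), float("nan")
    else:
        rho, p = stats.spearmanr(latents, totals)

    per_year: dict[int, float] = {}
    years = sorted({t.year for t in panel.truth})
    for year in years:
        idx = [k for k, t in enumerate(panel.truth) if t.year == year]
        lat, tot = latents[idx], totals[idx]
        per_year[year] = (
            float(stats.spearmanr(lat, tot)[0]) if np.ptp(lat) > 0 and np.ptp(tot) > 0 else float("nan")
        )

    cells = 0
    branch_hits = 0
    point_hits = 0
    for t, card in zip(panel.truth, cards):
        for ind_id, branch in t.branches.items():
            cells += 1
            sc = card.indicators[ind_id]
            branch_hits += sc.branch_id == branch
            point_hits += sc.points == t.points[ind_id]
    return RecoveryReport(
        spearman_rho=float(rho),
        spearman_p=float(p),
        per_year_rho=per_year,
        branch_agreement=branch_hits / cells,
        points_agreement=point_hits / cells,
        n=len(panel.truth),
    )
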