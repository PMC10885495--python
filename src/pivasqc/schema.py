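"""Submission schema for quarterly PIVAS reporting data.

A submission is one facility-period record over 67 data items grouped into
six aspects:

======  ============================  =====
aspect  meaning                       items
======  ============================  =====
A       basic information             12
B       hardware management           12
C       personnel management          10
D       work-efficiency management    19
E       infection-control management  11
F       information management        3
======  ============================  =====

The module provides typed parsing (:func:`parse_submission`), serialization,
controlled vocabularies for the categorical items, and the audit rules that
gate acceptance of a submission (:func:`audit_submission`).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

__all__ = [
    "ItemDef",
    "Vocabulary",
    "SubmissionSchema",
    "Period",
    "Submission",
    "Finding",
    "AuditReport",
    "SubmissionParseError",
    "default_schema",
    "parse_submission",
    "serialize_submission",
    "audit_submission",
    "aggregate_year",
    "read_submissions_csv",
    "write_submissions_csv",
]

SCHEMA_VERSION = "1.0.0"

# Data-type tags understood by the coercion layer.
STR = "str"
INT = "int"
FLOAT = "float"
PERCENT = "percent"  # float constrained to [0, 100]
BOOL = "bool"
CATEGORY = "category"  # single token from a vocabulary
TOKENLIST = "tokenlist"  # delimiter-separated tokens (vocabulary-matched)
TIME = "time"  # free-form timestamp string

#: how an item combines when four quarterly records are rolled into a year
SUM, MEAN, LAST = "sum", "mean", "last"


class SubmissionParseError(ValueError):
    """Raised when a raw record cannot be coerced into a Submission."""


@dataclass(frozen=True)
class ItemDef:
    """Definition of a single data-collection item."""

    id: str
    aspect: str
    label: str
    unit: str
    dtype: str
    required: bool = True
    vocabulary: str | None = None
    aggregate: str = LAST


@dataclass(frozen=True)
class Vocabulary:
    """An ordered controlled vocabulary.

    ``ordered_levels`` is ranked from lowest to highest where ordering is
    meaningful (titles, degrees); ``threshold`` names the level used as a
    pass mark by rubric branches, and must be a member of the levels.
    ``traceable`` flags the levels (equipment kinds) that count toward
    traceability capacity.
    """

    name: str
    ordered_levels: tuple[str, ...]
    threshold: str | None = None
    traceable: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if len(set(self.ordered_levels)) != len(self.ordered_levels):
            raise ValueError(f"vocabulary {self.name!r} has duplicate levels")
        if self.threshold is not None and self.threshold not in self.ordered_levels:
            raise ValueError(
                f"vocabulary {self.name!r}: threshold {self.threshold!r} not a level"
            )

    def rank(self, level: str) -> int:
        return self.ordered_levels.index(level)

    def at_or_above_threshold(self, level: str) -> bool:
        if self.threshold is None:
            raise ValueError(f"vocabulary {self.name!r} has no threshold level")
        return self.rank(level) >= self.rank(self.threshold)


_TOKEN_SPLIT = re.compile(r"[,;、/|]+")


def split_tokens(raw: str) -> list[str]:
    """Split a delimiter-separated token field into stripped tokens."""
    return [t.strip().lower() for t in _TOKEN_SPLIT.split(raw) if t.strip()]


def match_tokens(raw: str, vocab: Vocabulary) -> tuple[list[str], list[str]]:
    """Match a token field against a vocabulary.

    Returns ``(known, unknown)`` where *known* is the de-duplicated list of
    recognised levels in vocabulary order and *unknown* the unmatched tokens.
    """
    tokens = split_tokens(raw)
    levels = {lv.lower(): lv for lv in vocab.ordered_levels}
    known: list[str] = []
    unknown: list[str] = []
    for tok in tokens:
        if tok in levels:
            if levels[tok] not in known:
                known.append(levels[tok])
        else:
            unknown.append(tok)
    known.sort(key=vocab.rank)
    return known, unknown


# ---------------------------------------------------------------------------
# default schema: the 67 items
# ---------------------------------------------------------------------------

def _items() -> list[ItemDef]:
    A, B, C, D, E, F = "A", "B", "C", "D", "E", "F"
    out = [
        # -- aspect A: basic information ------------------------------------
        ItemDef("A01", A, "name of medical institution", "", STR),
        ItemDef("A02", A, "address", "", STR),
        ItemDef("A03", A, "legal representative", "", STR, required=False),
        ItemDef("A04", A, "director of pharmacy department", "", STR, required=False),
        ItemDef("A05", A, "fixed telephone number", "", INT, required=False),
        ItemDef("A06", A, "reporter", "", STR, required=False),
        ItemDef("A07", A, "position of reporter", "", STR, required=False),
        ItemDef("A08", A, "hospital grade", "", CATEGORY, vocabulary="hospital_grade"),
        ItemDef("A09", A, "postal code", "", INT),
        ItemDef("A10", A, "director of medical institution", "", STR, required=False),
        ItemDef("A11", A, "phone number", "", INT, required=False),
        ItemDef("A12", A, "start operating time", "", TIME),
        # -- aspect B: hardware management ----------------------------------
        ItemDef("B01", B, "working area", "m2", FLOAT),
        ItemDef("B02", B, "total number of beds", "bed", INT),
        ItemDef("B03", B, "number of hospital wards", "unit", INT),
        ItemDef("B04", B, "beds provided (temporary prescription)", "unit", INT),
        ItemDef("B05", B, "number of clean benches", "unit", INT),
        ItemDef("B06", B, "number of air conditioners", "unit", INT),
        ItemDef("B07", B, "number of fans", "unit", INT),
        ItemDef("B08", B, "number of horizontal laminar flow consoles", "unit", INT),
        ItemDef("B09", B, "rest area", "m2", FLOAT),
        ItemDef("B10", B, "beds provided by PIVAS", "bed", INT),
        ItemDef("B11", B, "beds provided (long-term prescription)", "bed", INT),
        ItemDef("B12", B, "number of biosafety cabinets", "unit", INT),
        # -- aspect C: personnel management ---------------------------------
        ItemDef("C01", C, "number of assistant staff", "people", INT),
        # training counts are reported year-to-date, so a yearly roll-up takes
        # the latest value rather than summing quarters
        ItemDef("C02", C, "trainings at or above municipal level", "times", INT),
        ItemDef("C03", C, "people trained at or above municipal level", "people", INT),
        ItemDef("C04", C, "beds provided by PIVAS", "bed", INT),
        ItemDef("C05", C, "degree of director", "", CATEGORY, vocabulary="degree"),
        ItemDef("C06", C, "number of nurses", "people", INT),
        ItemDef("C07", C, "trainings in hospital", "times", INT),
        ItemDef("C08", C, "people trained in hospital", "people", INT),
        ItemDef("C09", C, "title of director", "", CATEGORY, vocabulary="director_title"),
        ItemDef("C10", C, "number of pharmacists", "people", INT),
        # -- aspect D: work-efficiency management ---------------------------
        ItemDef("D01", D, "total infusions prepared", "bag", INT, aggregate=SUM),
        ItemDef("D02", D, "antibiotics dispensed", "bag", INT, aggregate=SUM),
        ItemDef("D03", D, "anticancer drugs dispensed", "bag", INT, aggregate=SUM),
        ItemDef("D04", D, "daily prescriptions reviewed per person", "piece", INT, aggregate=MEAN),
        ItemDef("D05", D, "daily average dispensing, long-term prescriptions", "bag", INT, aggregate=MEAN),
        ItemDef("D06", D, "unreasonable prescriptions", "piece", INT, aggregate=SUM),
        ItemDef("D07", D, "disposal of unreasonable prescriptions", "", CATEGORY, vocabulary="disposal"),
        ItemDef("D08", D, "errors in displaying", "bag", INT, aggregate=SUM),
        ItemDef("D09", D, "disposable syringes used", "unit", INT, aggregate=SUM),
        ItemDef("D10", D, "total infusion distribution", "bag", INT, aggregate=SUM),
        ItemDef("D11", D, "general drugs dispensed", "bag", INT, aggregate=SUM),
        ItemDef("D12", D, "parenteral nutrition dispensed", "bag", INT, aggregate=SUM),
        ItemDef("D13", D, "daily infusion preparations per person", "bag", INT, aggregate=MEAN),
        ItemDef("D14", D, "total prescriptions", "piece", INT, aggregate=SUM),
        ItemDef("D15", D, "daily average dispensing, temporary prescriptions", "bag", INT, aggregate=MEAN),
        ItemDef("D16", D, "proportion of unreasonable prescriptions", "%", PERCENT, aggregate=MEAN),
        ItemDef("D17", D, "unreasonable prescriptions physicians agreed to modify", "piece", INT, aggregate=SUM),
        ItemDef("D18", D, "prescription review errors", "piece", INT, aggregate=SUM),
        ItemDef("D19", D, "wrong dispensings", "bag", INT, aggregate=SUM),
        # -- aspect E: infection-control management -------------------------
        ItemDef("E01", E, "comprehensive cleaning frequency", "times", INT, aggregate=SUM),
        ItemDef("E02", E, "humidity qualification rate", "%", PERCENT, aggregate=MEAN),
        ItemDef("E03", E, "microorganism qualification rate", "%", PERCENT, aggregate=MEAN),
        ItemDef("E04", E, "primary air-filter maintenances", "times", INT, aggregate=SUM),
        ItemDef("E05", E, "medium-efficiency air-filter maintenances", "times", INT, aggregate=SUM),
        ItemDef("E06", E, "high-efficiency air-filter maintenances", "times", INT, aggregate=SUM),
        ItemDef("E07", E, "temperature qualification rate", "%", PERCENT, aggregate=MEAN),
        ItemDef("E08", E, "pressure qualification rate", "%", PERCENT, aggregate=MEAN),
        ItemDef("E09", E, "cleanliness detections", "times", INT, aggregate=SUM),
        ItemDef("E10", E, "disinfectant replacements", "times", INT, aggregate=SUM),
        ItemDef("E11", E, "disinfection methods", "", TOKENLIST, vocabulary="disinfection"),
        # -- aspect F: information management -------------------------------
        ItemDef("F01", F, "automatic equipment", "", TOKENLIST, vocabulary="equipment"),
        ItemDef("F02", F, "information systems configured", "", BOOL),
        ItemDef("F03", F, "clinical-records management system configured", "", BOOL),
    ]
    return out


def _vocabularies() -> dict[str, Vocabulary]:
    return {
        "hospital_grade": Vocabulary(
            "hospital_grade",
            ("second-level", "second-level A", "third-level", "third-level A"),
        ),
        "director_title": Vocabulary(
            "director_title",
            (
                "junior pharmacist",
                "pharmacist",
                "supervising pharmacist",
                "associate chief pharmacist",
                "chief pharmacist",
            ),
            threshold="supervising pharmacist",
        ),
        "degree": Vocabulary(
            "degree",
            ("secondary school", "associate degree", "bachelor", "master", "doctor"),
            threshold="bachelor",
        ),
        "disposal": Vocabulary("disposal", ("packing", "returning")),
        "disinfection": Vocabulary(
            "disinfection",
            ("ethanol", "ultraviolet", "chlorine dioxide", "hydrogen peroxide", "ozone"),
        ),
        "equipment": Vocabulary(
            "equipment",
            (
                "drug dispensing scanner",
                "label printing machine",
                "infusion sorting machine",
                "automatic dispensing robot",
                "intelligent medicine cabinet",
                "automatic labelling machine",
                "infusion sealing machine",
                "prescription review workstation",
                "batch scheduling system terminal",
                "barcode verification station",
                "automatic capping machine",
                "intelligent delivery cart",
                "vertical flow clean bench",
                "automated syringe filler",
                "waste tracking terminal",
                "cold-chain monitoring unit",
                "automatic warehouse shuttle",
                "dose verification camera",
                "air-shower pass box",
                "environmental logger",
            ),
            # kinds that count toward traceability capacity
            traceable=frozenset(
                {
                    "drug dispensing scanner",
                    "label printing machine",
                    "infusion sorting machine",
                    "automatic dispensing robot",
                    "intelligent medicine cabinet",
                    "automatic labelling machine",
                    "infusion sealing machine",
                    "prescription review workstation",
                    "batch scheduling system terminal",
                    "barcode verification station",
                    "automatic capping machine",
                    "intelligent delivery cart",
                    "vertical flow clean bench",
                    "automated syringe filler",
                    "waste tracking terminal",
                    "cold-chain monitoring unit",
                    "automatic warehouse shuttle",
                    "dose verification camera",
                }
            ),
        ),
    }


@dataclass(frozen=True)
class SubmissionSchema:
    """The full item registry plus controlled vocabularies."""

    items: dict[str, ItemDef]
    vocabularies: dict[str, Vocabulary]
    version: str = SCHEMA_VERSION

    def aspect_items(self, aspect: str) -> list[ItemDef]:
        return [it for it in self.items.values() if it.aspect == aspect]

    @property
    def aspect_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for it in self.items.values():
            sizes[it.aspect] = sizes.get(it.aspect, 0) + 1
        return sizes

    def required_items(self) -> list[str]:
        return [i for i, it in self.items.items() if it.required]


_DEFAULT_SCHEMA: SubmissionSchema | None = None


def default_schema() -> SubmissionSchema:
    """Return the shipped 67-item schema (cached singleton)."""
    global _DEFAULT_SCHEMA
    if _DEFAULT_SCHEMA is None:
        items = _items()
        _DEFAULT_SCHEMA = SubmissionSchema(
            items={it.id: it for it in items}, vocabularies=_vocabularies()
        )
        assert len(_DEFAULT_SCHEMA.items) == 67
    return _DEFAULT_SCHEMA


# ---------------------------------------------------------------------------
# submissions
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Period:
    """A reporting period: a calendar quarter, or a whole year (quarter=0)."""

    year: int
    quarter: int

    def __post_init__(self) -> None:
        if self.quarter not in (0, 1, 2, 3, 4):
            raise ValueError(f"quarter must be 0 (annual) or 1-4, got {self.quarter}")

    @property
    def is_annual(self) -> bool:
        return self.quarter == 0

    @property
    def weeks(self) -> float:
        return 52.0 if self.is_annual else 13.0

    @property
    def days(self) -> float:
        return 364.0 if self.is_annual else 91.0

    def __str__(self) -> str:
        return f"{self.year}" if self.is_annual else f"{self.year}Q{self.quarter}"

    @classmethod
    def parse(cls, text: str) -> "Period":
        text = text.strip()
        if "Q" in text:
            year, quarter = text.split("Q", 1)
            return cls(int(year), int(quarter))
        return cls(int(text), 0)


@dataclass
class Submission:
    """One facility-period record over the 67 data items."""

    facility_id: str
    period: Period
    items: dict[str, Any] = field(default_factory=dict)

    def get(self, item_id: str, default: Any = None) -> Any:
        return self.items.get(item_id, default)

    @property
    def id(self) -> str:
        return f"{self.facility_id}:{self.period}"


_TRUE = {"1", "true", "yes", "y"}
_FALSE = {"0", "false", "no", "n", ""}


def _coerce(item: ItemDef, raw: Any, schema: SubmissionSchema) -> Any:
    if raw is None:
        raise SubmissionParseError(f"{item.id} is None")
    if item.dtype == INT:
        try:
            v = int(str(raw).strip())
        except ValueError:
            raise SubmissionParseError(
                f"{item.id} expects int ({item.unit or 'count'}), got {raw!r}"
            ) from None
        return v
    if item.dtype in (FLOAT, PERCENT):
        try:
            v = float(str(raw).strip())
        except ValueError:
            raise SubmissionParseError(
                f"{item.id} expects float ({item.unit or 'value'}), got {raw!r}"
            ) from None
        return v
    if item.dtype == BOOL:
        if isinstance(raw, bool):
            return raw
        s = str(raw).strip().lower()
        if s in _TRUE:
            return True
        if s in _FALSE:
            return False
        raise SubmissionParseError(f"{item.id} expects boolean flag, got {raw!r}")
    if item.dtype == CATEGORY:
        s = str(raw).strip()
        vocab = schema.vocabularies[item.vocabulary]  # type: ignore[index]
        for lv in vocab.ordered_levels:
            if lv.lower() == s.lower():
                return lv
        raise SubmissionParseError(
            f"{item.id} expects one of {list(vocab.ordered_levels)}, got {raw!r}"
        )
    # STR / TIME / TOKENLIST are stored verbatim
    return str(raw)


_META_KEYS = ("facility_id", "year", "quarter")


def parse_submission(
    record: Mapping[str, Any],
    schema: SubmissionSchema | None = None,
    *,
    facility_id: str | None = None,
    period: Period | None = None,
    on_unknown: str = "error",
) -> Submission:
    """Parse a raw key→value mapping into a typed :class:`Submission`.

    ``record`` keys are item identifiers (``A01``…``F03``); the metadata keys
    ``facility_id``, ``year`` and ``quarter`` may also be present in-band.
    Numeric strings are coerced per the declared item type. Empty values are
    treated as absent (missingness is an audit concern, not a parse error).

    Parameters
    ----------
    on_unknown
        ``"error"`` rejects unknown keys, ``"warn"`` ignores them.
    """
    schema = schema or default_schema()
    rec = dict(record)
    fid = facility_id if facility_id is not None else rec.pop("facility_id", None)
    if period is None:
        try:
            year = int(rec.pop("year"))
            quarter = int(rec.pop("quarter", 0))
        except KeyError:
            raise SubmissionParseError("record lacks a period (year/quarter)") from None
        period = Period(year, quarter)
    else:
        rec.pop("year", None)
        rec.pop("quarter", None)
    if fid is None:
        raise SubmissionParseError("record lacks a facility_id")

    items: dict[str, Any] = {}
    for key, raw in rec.items():
        if key not in schema.items:
            if on_unknown == "error":
                raise SubmissionParseError(f"unknown item identifier {key!r}")
            continue
        if raw is None or (isinstance(raw, str) and not raw.strip()):
            continue  # absent
        items[key] = _coerce(schema.items[key], raw, schema)
    return Submission(facility_id=str(fid), period=period, items=items)


def serialize_submission(sub: Submission, schema: SubmissionSchema | None = None) -> dict[str, str]:
    """Flatten a Submission to a string-valued record (inverse of parsing)."""
    schema = schema or default_schema()
    out: dict[str, str] = {
        "facility_id": sub.facility_id,
        "year": str(sub.period.year),
        "quarter": str(sub.period.quarter),
    }
    for item_id in schema.items:
        if item_id not in sub.items:
            out[item_id] = ""
            continue
        v = sub.items[item_id]
        if isinstance(v, bool):
            out[item_id] = "1" if v else "0"
        elif isinstance(v, float):
            out[item_id] = repr(v)
        else:
            out[item_id] = str(v)
    return out


# ---------------------------------------------------------------------------
# audit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Finding:
    item_id: str
    rule_id: str
    severity: str  # "error" | "warning"
    message: str


@dataclass
class AuditReport:
    submission_id: str
    findings: list[Finding]

    @property
    def status(self) -> str:
        return "fail" if any(f.severity == "error" for f in self.findings) else "pass"

    @property
    def passed(self) -> bool:
        return self.status == "pass"

    def errors(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "error"]


def _rule_completeness(sub: Submission, schema: SubmissionSchema) -> list[Finding]:
    out = []
    for item_id in schema.required_items():
        if item_id not in sub.items:
            out.append(
                Finding(item_id, "completeness", "error", f"required item {item_id} is missing")
            )
    return out


def _rule_ranges(sub: Submission, schema: SubmissionSchema) -> list[Finding]:
    out = []
    for item_id, value in sub.items.items():
        item = schema.items[item_id]
        if item.dtype == INT and not isinstance(value, bool) and value < 0:
            out.append(Finding(item_id, "range", "error", f"{item_id} count {value} < 0"))
        elif item.dtype == PERCENT and not (0.0 <= value <= 100.0):
            out.append(
                Finding(item_id, "range", "error", f"{item_id} percentage {value} outside [0, 100]")
            )
        elif item.dtype == FLOAT and value < 0:
            out.append(Finding(item_id, "range", "error", f"{item_id} value {value} < 0"))
    return out


def _rule_consistency(sub: Submission, schema: SubmissionSchema) -> list[Finding]:
    out = []
    g = sub.get

    d06, d14, d16, d17 = g("D06"), g("D14"), g("D16"), g("D17")
    if d06 is not None and d14 is not None and d06 > d14:
        out.append(
            Finding(
                "D06", "consistency.D06<=D14", "error",
                f"unreasonable prescriptions D06={d06} exceed total prescriptions D14={d14}",
            )
        )
    if d17 is not None and d06 is not None and d17 > d06:
        out.append(
            Finding(
                "D17", "consistency.D17<=D06", "error",
                f"modified prescriptions D17={d17} exceed unreasonable prescriptions D06={d06}",
            )
        )
    # D16 is redundant with D06/D14; tolerate 0.5 percentage points of slack
    if d16 is not None and d06 is not None and d14 not in (None, 0):
        implied = 100.0 * d06 / d14
        if abs(d16 - implied) > 0.5:
            out.append(
                Finding(
                    "D16", "consistency.D16~D06/D14", "warning",
                    f"D16={d16:.2f}% differs from 100*D06/D14={implied:.2f}% by more than 0.5pp",
                )
            )

    b02, b10 = g("B02"), g("B10")
    if b02 is not None and b10 is not None and b10 > b02:
        out.append(
            Finding(
                "B10", "consistency.B02>B10", "error",
                f"beds served by PIVAS B10={b10} violate the B02 > B10 ordering (B02={b02})",
            )
        )

    staff = sum(v for v in (g("C01"), g("C06"), g("C10")) if v is not None)
    for item_id in ("C03", "C08"):
        v = g(item_id)
        if v is not None and v > staff:
            out.append(
                Finding(
                    item_id, f"consistency.{item_id}<=staff", "warning",
                    f"{item_id}={v} trained people exceed total staff {staff}",
                )
            )
    return out


DEFAULT_AUDIT_RULES = (_rule_completeness, _rule_ranges, _rule_consistency)


def audit_submission(
    sub: Submission,
    rules: Iterable = DEFAULT_AUDIT_RULES,
    schema: SubmissionSchema | None = None,
) -> AuditReport:
    """Verify integrity and validity of a parsed submission.

    Violations become findings, never exceptions; the report fails iff at
    least one finding has error severity. The check is pure: applying it
    twice, or with the rules in any order, yields the same report.
    """
    schema = schema or default_schema()
    findings: list[Finding] = []
    for rule in rules:
        findings.extend(rule(sub, schema))
    findings.sort(key=lambda f: (f.item_id, f.rule_id, f.severity, f.message))
    return AuditReport(submission_id=sub.id, findings=findings)


# ---------------------------------------------------------------------------
# yearly aggregation
# ---------------------------------------------------------------------------

def aggregate_year(subs: Sequence[Submission], schema: SubmissionSchema | None = None) -> Submission:
    """Roll quarterly submissions of one facility-year into an annual record.

    Flow counts are summed and annualized (scaled by 4/k when only k < 4
    quarters are on file, so per-day and per-week readings stay comparable),
    daily averages and rates are averaged, and stock items (areas, bed
    counts, staffing, categorical fields) take their latest reported value.
    The result carries ``quarter=0``.
    """
    schema = schema or default_schema()
    if not subs:
        raise ValueError("no submissions to aggregate")
    fids = {s.facility_id for s in subs}
    years = {s.period.year for s in subs}
    if len(fids) != 1 or len(years) != 1:
        raise ValueError(f"submissions span facilities {fids} / years {years}")
    ordered = sorted(subs, key=lambda s: s.period)
    items: dict[str, Any] = {}
    for item_id, item in schema.items.items():
        values = [s.items[item_id] for s in ordered if item_id in s.items]
        if not values:
            continue
        if item.aggregate == SUM:
            annualized = sum(values) * 4.0 / len(values)
            items[item_id] = round(annualized) if item.dtype == INT else annualized
        elif item.aggregate == MEAN:
            mean = sum(values) / len(values)
            items[item_id] = mean if item.dtype in (FLOAT, PERCENT) else round(mean)
        else:
            items[item_id] = values[-1]
    return Submission(facility_id=ordered[0].facility_id, period=Period(ordered[0].period.year, 0), items=items)


# ---------------------------------------------------------------------------
# delimited-text ingest / export
# ---------------------------------------------------------------------------

def read_submissions_csv(path, schema: SubmissionSchema | None = None, on_unknown: str = "error") -> list[Submission]:
    """Read submissions from a CSV with header ``facility_id,year,quarter,A01,…``."""
    schema = schema or default_schema()
    subs = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(row for row in fh if not row.startswith("#"))
        header = next(reader)
        seen: set[str] = set()
        for col in header:
            if col in seen:
                raise SubmissionParseError(f"duplicate column {col!r} in {path}")
            seen.add(col)
        for row in reader:
            if not any(cell.strip() for cell in row):
                continue
            rec = dict(zip(header, row))
            subs.append(parse_submission(rec, schema, on_unknown=on_unknown))
    return subs


def write_submissions_csv(path, subs: Sequence[Submission], schema: SubmissionSchema | None = None) -> None:
    schema = schema or default_schema()
    header = list(_META_KEYS) + list(schema.items)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for sub in subs:
            rec = serialize_submission(sub, schema)
            writer.writerow([rec.get(c, "") for c in header])
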