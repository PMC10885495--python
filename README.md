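# pivasqc

Quality-control scoring engine for regional PIVAS (pharmacy intravenous
admixture services) reporting data.

Hospitals' PIVAS units report a 67-item quarterly record covering basic
information, hardware, personnel, work efficiency, infection control and
information management. `pivasqc` validates those records against typed
schema and audit rules, scores them on a 20-indicator evaluation matrix
(category maxima 11 / 14 / 49 / 13 / 13, total 100), benchmarks facilities
against their region (min/mean/max, attainment rates, radar datasets), and
tracks a facility panel over years (mean ± SD tables plus paired sign-flip
permutation comparisons). A seeded synthetic-cohort generator makes the
whole pipeline exercisable without any real hospital data.

## Library overview

| module              | contents                                                        |
| ------------------- | --------------------------------------------------------------- |
| `pivasqc.schema`    | 67-item schema, vocabularies, parsing, audit rules, CSV ingest  |
| `pivasqc.rubric`    | derived metrics, 20 indicator branch tables, scorecards         |
| `pivasqc.benchmark` | regional aggregation, attainment rates, radar datasets          |
| `pivasqc.trends`    | yearly summaries, Shapiro–Wilk check, permutation comparisons   |
| `pivasqc.synthetic` | branch-first seeded cohort generator + recovery diagnostics     |
| `pivasqc.cli`       | the `pivasqc` command-line pipeline                             |

```python
from pivasqc import (CohortConfig, generate_cohort, score_submission,
                     aggregate_region, yearly_summary)

panel = generate_cohort(CohortConfig(n_facilities=15, years=3, seed=42))
cards = [score_submission(s, refs=panel.refs) for s in panel.yearly_submissions()]
bench = aggregate_region(cards)
table = yearly_summary(cards)
```

Regional reference averages (daily deployment, bed infusion, syringe usage,
unreasonable-prescription rate, disposition rate, error rate) are injectable
configuration; when not supplied they are derived from the scored cohort
itself and provenance-tagged.

## Command line

```sh
pivasqc simulate  --out sim --seed 7 --noise 0.1       # synthetic cohort
pivasqc validate  --in sim/submissions.csv --strict    # parse + audit
pivasqc score     --in sim/submissions.csv --refs sim/refs.yaml \
                  --out scored --annual                # scorecards
pivasqc benchmark --cards scored/scorecards.json --out bench
pivasqc trend     --cards scored/scorecards.json --out trend --seed 3
pivasqc report    --cards scored/scorecards.json --out report
```

All artifacts are plain text (CSV/JSON/YAML), written atomically, and embed
the rubric version plus a configuration hash; fixed seeds reproduce every
artifact byte for byte.

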