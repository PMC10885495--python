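import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pivasqc.rubric import (
    CATEGORIES,
    CATEGORY_MAXIMA,
    UNDEFINED,
    RegionalReference,
    ScoringError,
    derive_metrics,
    is_defined,
    required_working_area,
    rubric_from_config,
    rubric_maxima,
    rubric_to_config,
    score_indicator,
    score_submission,
)

from conftest import make_submission, worst_submission


class TestDerivedMetrics:
    def test_daily_deployment_sum(self, schema):
        m = derive_metrics(make_submission(schema, D05=600, D15=200), schema)
        assert m.m_daily == 800

    def test_training_ratio_hand_arithmetic(self, schema):
        # (2 + 3) / (4 + 1) = 1.0
        m = derive_metrics(make_submission(schema, C02=2, C07=3, C03=4, C08=1), schema)
        assert m.training_ratio == 1.0

    def test_zero_denominator_is_undefined(self, schema):
        m = derive_metrics(make_submission(schema, D06=0, D17=0, D16=0.0), schema)
        assert m.disposition_rate is UNDEFINED

    def test_error_rate_groups_all_three_counts(self, schema):
        m = derive_metrics(make_submission(schema, D08=40, D18=30, D19=30, D01=72800), schema)
        assert m.error_rate == pytest.approx(100 / 72800)

    def test_bed_infusion_is_per_day(self, schema):
        m = derive_metrics(make_submission(schema, D10=68250, B10=300), schema)
        assert m.bed_infusion == pytest.approx(68250 / (300 * 91))

    def test_equipment_and_traceable_counts(self, schema, submission):
        m = derive_metrics(submission, schema)
        assert m.equipment_count == 7
        assert m.traceable_count == 7
        assert m.disinfection_methods == 2

    def test_unknown_disinfection_tokens_count_once(self, schema):
        sub = make_submission(schema, E11="ethanol, magic spray, other goo")
        m = derive_metrics(sub, schema)
        assert m.disinfection_methods == 2  # ethanol + one for unknowns

    def test_explicit_no_equipment(self, schema):
        m = derive_metrics(make_submission(schema, F01="none"), schema)
        assert m.equipment_count == 0
        assert m.traceable_count == 0


class TestWorkingAreaRequirement:
    @pytest.mark.parametrize(
        "m_daily,expected",
        [(800, 300), (1000, 300), (1500, 300), (2000, 300), (2500, 500),
         (3000, 500), (3001, 700), (3500, 700), (4000, 750), (5000, 850)],
    )
    def test_tiers(self, m_daily, expected):
        assert required_working_area(m_daily, {}) == expected


def _score(schema, rubric, refs, sub, ind_id, policy="lenient"):
    metrics = derive_metrics(sub, schema)
    return score_indicator(metrics, sub, rubric[ind_id], refs, schema, policy=policy)


class TestBranchExamples:
    """Worked examples from the published branch tables."""

    def test_working_area_800_bags_350m2(self, schema, rubric, refs):
        sub = make_submission(schema, D05=600, D15=200, B01=350)
        assert _score(schema, rubric, refs, sub, "H1").points == 5

    def test_reviewed_450_scores_6(self, schema, rubric, refs):
        sub = make_submission(schema, D04=450)
        assert _score(schema, rubric, refs, sub, "W7").points == 6

    def test_temporary_rate_6pct_scores_5(self, schema, rubric, refs):
        sub = make_submission(schema, D05=1000, D15=60)
        sc = _score(schema, rubric, refs, sub, "W6")
        assert (sc.points, sc.branch_id) == (5, "above-5pct")

    def test_training_ratio_1_scores_2(self, schema, rubric, refs):
        sub = make_submission(schema, C02=5, C07=5, C03=4, C08=6)
        assert _score(schema, rubric, refs, sub, "P1").points == 2

    def test_single_disinfection_method_scores_0(self, schema, rubric, refs):
        sub = make_submission(schema, E11="ethanol")
        assert _score(schema, rubric, refs, sub, "I3").points == 0

    def test_all_nurses_scores_0(self, schema, rubric, refs):
        sub = make_submission(schema, C10=0, C06=8)
        assert _score(schema, rubric, refs, sub, "P2").points == 0

    def test_director_below_threshold_scores_2(self, schema, rubric, refs):
        sub = make_submission(schema, C09="pharmacist")
        assert _score(schema, rubric, refs, sub, "P3").points == 2

    def test_deployment_exactly_average_scores_4(self, schema, rubric, refs):
        sub = make_submission(schema, D05=1400, D15=100)  # m = 1500 = A
        sc = _score(schema, rubric, refs, sub, "W2")
        assert (sc.points, sc.branch_id) == (4, "two-thirds-to-avg")

    def test_infusion_classes_are_additive(self, schema, rubric, refs):
        sub = make_submission(schema, D02=0, D03=0, D11=100, D12=100)
        sc = _score(schema, rubric, refs, sub, "W1")
        assert sc.points == 5  # parenteral nutrition 3 + general 2
        assert sc.branch_id == "classes:pn+gd"

    def test_tracing_boundary_exactly_2_scores_3(self, schema, rubric, refs):
        # 6 traceable kinds on 3 consoles -> ratio exactly 2 -> (1, 2] branch
        kinds = ("drug dispensing scanner, label printing machine, infusion sorting machine, "
                 "automatic dispensing robot, intelligent medicine cabinet, automatic labelling machine")
        sub = make_submission(schema, F01=kinds)
        sc = _score(schema, rubric, refs, sub, "N2")
        assert (sc.points, sc.branch_id) == (3, "1-2")


class TestMaxima:
    def test_per_indicator_maxima_as_printed(self, rubric):
        maxima = rubric_maxima(rubric)
        assert [maxima[i] for i in ("H1", "H2", "H3")] == [5, 1, 5]
        assert [maxima[i] for i in ("P1", "P2", "P3")] == [5, 5, 4]
        assert [maxima[f"W{k}"] for k in range(1, 10)] == [10, 5, 3, 5, 5, 5, 6, 5, 5]
        assert [maxima[i] for i in ("I1", "I2", "I3")] == [5, 5, 3]
        assert [maxima[i] for i in ("N1", "N2")] == [8, 5]

    def test_category_maxima(self, rubric):
        maxima = rubric_maxima(rubric)
        assert {c: maxima[c] for c in CATEGORIES} == CATEGORY_MAXIMA

    def test_total_is_100(self, rubric):
        assert rubric_maxima(rubric)["total"] == 100

    def test_director_max_is_4(self, rubric):
        assert rubric["P3"].max_points == 4


class TestScoreSubmission:
    def test_scorecard_has_20_indicators_and_conserves_total(self, schema, rubric, refs, submission):
        card = score_submission(submission, rubric, refs, schema)
        assert len(card.indicators) == 20
        assert card.total == pytest.approx(sum(s.points for s in card.indicators.values()))
        assert card.total == pytest.approx(sum(card.category_subtotals.values()))

    def test_deterministic(self, schema, rubric, refs, submission):
        c1 = score_submission(submission, rubric, refs, schema)
        c2 = score_submission(submission, rubric, refs, schema)
        assert c1.to_dict() == c2.to_dict()

    def test_worst_branch_everywhere_totals_12(self, schema, rubric, refs):
        card = score_submission(worst_submission(schema), rubric, refs, schema)
        assert card.annotations == []
        assert card.total == 12

    def test_lenient_zeroes_and_annotates_undefined(self, schema, rubric, refs, record):
        del record["D04"]
        from pivasqc.schema import parse_submission

        sub = parse_submission(record, schema)
        card = score_submission(sub, rubric, refs, schema, policy="lenient")
        assert card.indicators["W7"].points == 0
        assert card.indicators["W7"].branch_id == "undefined-input"
        assert any("W7" in a for a in card.annotations)

    def test_strict_raises_naming_indicator_and_item(self, schema, rubric, refs, record):
        del record["D04"]
        from pivasqc.schema import parse_submission

        sub = parse_submission(record, schema)
        with pytest.raises(ScoringError, match="W7.*D04"):
            score_submission(sub, rubric, refs, schema, policy="strict")


class TestMonotonicity:
    def test_raising_d04_never_raises_w7(self, schema, rubric, refs):
        points = [
            _score(schema, rubric, refs, make_submission(schema, D04=d), "W7").points
            for d in range(100, 1200, 25)
        ]
        assert points == sorted(points, reverse=True)

    def test_raising_training_ratio_never_lowers_p1(self, schema, rubric, refs):
        points = []
        for sessions in range(0, 30):
            sub = make_submission(schema, C02=sessions, C07=0, C03=5, C08=5)
            points.append(_score(schema, rubric, refs, sub, "P1").points)
        assert points == sorted(points)

    def test_adding_drug_class_never_lowers_w1(self, schema, rubric, refs):
        base = dict(D02=0, D03=0, D11=0, D12=0)
        score0 = _score(schema, rubric, refs, make_submission(schema, **base), "W1").points
        for item in ("D02", "D03", "D11", "D12"):
            sub = make_submission(schema, **{**base, item: 100})
            assert _score(schema, rubric, refs, sub, "W1").points >= score0


class TestBranchExhaustiveness:
    def test_random_sweep_never_falls_through(self, schema, rubric, refs):
        rng = np.random.default_rng(1234)
        for _ in range(300):
            sub = make_submission(
                schema,
                B01=float(rng.uniform(0, 2000)),
                B09=float(rng.uniform(0, 100)) * (rng.random() < 0.5),
                B05=int(rng.integers(0, 5)), B08=int(rng.integers(0, 5)), B12=int(rng.integers(0, 5)),
                C02=int(rng.integers(0, 30)), C07=int(rng.integers(0, 30)),
                C03=int(rng.integers(0, 10)), C08=int(rng.integers(0, 10)),
                C10=int(rng.integers(0, 10)), C06=int(rng.integers(0, 10)),
                D04=int(rng.integers(0, 1500)),
                D05=int(rng.integers(1, 4000)), D15=int(rng.integers(0, 400)),
                D13=int(rng.integers(0, 300)),
                D06=0, D17=0, D16=float(rng.uniform(0, 10)),
                D08=int(rng.integers(0, 200)), D18=int(rng.integers(0, 200)),
                D19=int(rng.integers(0, 200)),
                E01=int(rng.integers(0, 40)),
                E04=int(rng.integers(0, 3)), E05=int(rng.integers(0, 3)), E06=int(rng.integers(0, 3)),
            )
            card = score_submission(sub, rubric, refs, schema, policy="lenient")
            assert len(card.indicators) == 20
            for ind_id, sc in card.indicators.items():
                assert 0 <= sc.points <= rubric[ind_id].max_points
                assert sc.branch_id


class TestRegionalReference:
    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError, match="positive"):
            RegionalReference(0, 1, 1, 1, 1, 1)

    def test_cohort_derived_provenance(self, schema, submission):
        refs = RegionalReference.from_cohort([submission], schema)
        assert refs.provenance == "cohort-derived"
        assert refs.avg_daily_deployment == 800

    def test_round_trip_dict(self, refs):
        assert RegionalReference.from_dict(refs.to_dict()) == refs


class TestRubricConfig:
    def test_round_trip_preserves_scoring(self, schema, rubric, refs, submission):
        rebuilt = rubric_from_config(rubric_to_config(rubric))
        c1 = score_submission(submission, rubric, refs, schema)
        c2 = score_submission(submission, rebuilt, refs, schema)
        assert c1.to_dict() == c2.to_dict()

    def test_param_override_changes_branch(self, schema, rubric, refs):
        config = rubric_to_config(rubric)
        config["indicators"]["W7"]["params"]["lo"] = 400
        config["version"] = "custom-1"
        custom = rubric_from_config(config)
        sub = make_submission(schema, D04=450)
        assert _score(schema, rubric, refs, sub, "W7").points == 6
        metrics = derive_metrics(sub, schema)
        assert score_indicator(metrics, sub, custom["W7"], refs, schema).points == 3


@given(st.floats(0.01, 0.99), st.floats(0.01, 0.99))
@settings(max_examples=50, deadline=None)
def test_p1_monotone_in_quality_of_ratio(r1, r2):
    """P1 points are a nondecreasing function of the training ratio."""
    from pivasqc.rubric import default_rubric
    from pivasqc.schema import default_schema
    from pivasqc.synthetic import default_reference_anchors

    schema, rubric, refs = default_schema(), default_rubric(), default_reference_anchors()
    lo, hi = sorted((r1, r2))
    subs = [make_submission(schema, C02=round(r * 1000), C07=0, C03=500, C08=500) for r in (lo, hi)]
    pts = [_score(schema, rubric, refs, s, "P1").points for s in subs]
    assert pts[0] <= pts[1]
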