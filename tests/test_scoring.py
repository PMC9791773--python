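"""Scoring rules, densification, filtering, and per-subject composition."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpdi.errors import CategoryMismatchError, DegenerateIntakeError
from cpdi.scoring import (
    DailyIntakeRecord,
    SubjectProfile,
    average_and_densify,
    filter_plausible_energy,
    score_adequacy,
    score_cohort,
    score_component,
    score_limitation,
    score_moderation,
    score_subject,
)
from cpdi.simulate import generate_targeted_subject
from cpdi.standards import AgeGroup

from oracles import TABLE_CUTOFFS, oracle_score

# densities meeting every max-score criterion for an OLD (4-5 y) child
MAX_SCORE_DENSITIES_OLD = {
    "vegetables": 179, "fruits": 107, "dairy": 250, "soybeans": 11,
    "aquatic_products": 14, "cereals": 100, "eggs": 19, "red_meat_poultry": 20,
    "vitamin_a": 500, "iron": 10, "snacks": 0,
}


def _record(sid="s1", day=1, energy=1000.0, **amounts):
    return DailyIntakeRecord(sid, day, energy, amounts)


class TestScoringRules:
    """The three piecewise-linear rules, anchored on the published examples."""

    def test_adequacy_worked_example(self, standard):
        dairy = standard.component("dairy")
        assert score_adequacy(200, dairy, AgeGroup.OLD) == pytest.approx(8.0, abs=1e-12)

    def test_moderation_worked_example(self, standard):
        cereals = standard.component("cereals")
        assert score_moderation(150, cereals, AgeGroup.YOUNG) == pytest.approx(5.0, abs=1e-12)

    def test_limitation_worked_example(self, standard):
        snacks = standard.component("snacks")
        assert score_limitation(45, snacks, AgeGroup.OLD) == pytest.approx(2.75, abs=1e-12)

    @pytest.mark.parametrize(
        "component_id, group, density, expected",
        [
            ("dairy", AgeGroup.OLD, 300, 10.0),          # capped at recommendation
            ("dairy", AgeGroup.OLD, 0, 0.0),
            ("fruits", AgeGroup.YOUNG, 41.5, 5.0),        # (41.5/83) x 10
            ("eggs", AgeGroup.OLD, 20, 10.0),             # inside 18-21
            ("cereals", AgeGroup.YOUNG, 0, 0.0),
            ("cereals", AgeGroup.YOUNG, 35.5, 5.0),       # (1-|1-35.5/71|) x 10
            ("cereals", AgeGroup.YOUNG, 250, 0.0),        # beyond 2 x upper
            ("snacks", AgeGroup.YOUNG, 0, 5.0),
            ("snacks", AgeGroup.OLD, 150, 0.0),
            ("vitamin_a", AgeGroup.OLD, 257, 2.5),        # interval is inclusive
            ("iron", AgeGroup.YOUNG, 50, 0.0),            # exactly 2 x upper -> linear 0
        ],
    )
    def test_spot_values(self, standard, component_id, group, density, expected):
        comp = standard.component(component_id)
        assert score_component(density, comp, group) == pytest.approx(expected, abs=1e-12)

    def test_category_dispatch_is_guarded(self, standard):
        with pytest.raises(CategoryMismatchError):
            score_adequacy(10, standard.component("cereals"), AgeGroup.YOUNG)
        with pytest.raises(CategoryMismatchError):
            score_moderation(10, standard.component("dairy"), AgeGroup.YOUNG)
        with pytest.raises(CategoryMismatchError):
            score_limitation(10, standard.component("iron"), AgeGroup.YOUNG)

    def test_negative_density_rejected(self, standard):
        with pytest.raises(ValueError):
            score_adequacy(-1, standard.component("dairy"), AgeGroup.OLD)


class TestGridOracleEquivalence:
    """Dense-grid agreement with an independently coded reading of the rules."""

    @pytest.mark.parametrize("component_id", sorted(TABLE_CUTOFFS))
    @pytest.mark.parametrize("group", [AgeGroup.YOUNG, AgeGroup.OLD])
    def test_matches_oracle_on_dense_grid(self, standard, component_id, group):
        comp = standard.component(component_id)
        category, _, young, old = TABLE_CUTOFFS[component_id]
        cut = young if group is AgeGroup.YOUNG else old
        scale = cut if category != "moderation" else cut[1]
        grid = np.linspace(0.0, 3.0 * scale, 10_000)
        for d in grid:
            impl = score_component(float(d), comp, group)
            assert impl == pytest.approx(
                oracle_score(component_id, group.value, float(d)), abs=1e-9
            )

    @pytest.mark.parametrize("component_id", sorted(TABLE_CUTOFFS))
    @pytest.mark.parametrize("group", [AgeGroup.YOUNG, AgeGroup.OLD])
    def test_monotonicity_and_bounds_on_grid(self, standard, component_id, group):
        comp = standard.component(component_id)
        category, max_score, young, old = TABLE_CUTOFFS[component_id]
        cut = young if group is AgeGroup.YOUNG else old
        scale = cut if category != "moderation" else cut[1]
        grid = np.linspace(0.0, 3.0 * scale, 10_000)
        scores = np.array([score_component(float(d), comp, group) for d in grid])
        assert np.all(scores >= 0) and np.all(scores <= max_score)
        if category == "adequacy":
            assert np.all(np.diff(scores) >= -1e-12)
        elif category == "limitation":
            assert np.all(np.diff(scores) <= 1e-12)
        else:
            lo, up = cut
            rising = grid[1:] <= lo
            falling = grid[:-1] >= up
            inner = (grid[:-1] > 0) & rising
            assert np.all(np.diff(scores)[inner] >= -1e-12)
            assert np.all(np.diff(scores)[falling] <= 1e-12)

    @pytest.mark.parametrize("component_id", ["cereals", "eggs", "red_meat_poultry",
                                              "vitamin_a", "iron"])
    @pytest.mark.parametrize("group", [AgeGroup.YOUNG, AgeGroup.OLD])
    def test_moderation_boundary_continuity(self, standard, component_id, group):
        comp = standard.component(component_id)
        cut = comp.cutoffs_for(group)
        M = comp.max_score
        assert score_component(cut.lower, comp, group) == M
        assert score_component(cut.upper, comp, group) == M
        assert score_component(2 * cut.upper, comp, group) == 0.0
        # approaching the boundaries stays continuous
        eps = 1e-7 * cut.upper
        assert score_component(cut.lower - eps, comp, group) == pytest.approx(M, abs=1e-4)
        assert score_component(cut.upper + eps, comp, group) == pytest.approx(M, abs=1e-4)


class TestEnergyFilter:
    def test_bounds_are_strict(self):
        records = [
            _record("below", energy=300.0),
            _record("at_min", energy=400.0),
            _record("typical", energy=1150.0),
            _record("at_max", energy=4000.0),
            _record("above", energy=4001.0),
        ]
        kept, excluded = filter_plausible_energy(records)
        assert sorted(kept) == ["at_max", "at_min", "typical"]
        reasons = {e.subject_id: e.reason for e in excluded}
        assert reasons == {"below": "energy_below_minimum", "above": "energy_above_maximum"}

    def test_filter_uses_mean_over_days(self):
        # days 200 and 700 average to 450 -> kept despite one low day
        records = [_record("kid", day=1, energy=200.0), _record("kid", day=2, energy=700.0)]
        kept, excluded = filter_plausible_energy(records)
        assert "kid" in kept and not excluded


class TestDensification:
    def test_identity_at_1000_kcal(self):
        dv = average_and_densify([_record(energy=1000.0, dairy=200.0)])
        assert dv.densities["dairy"] == pytest.approx(200.0)

    def test_three_day_hand_computed(self):
        recs = [
            _record(day=1, energy=1000.0, dairy=150.0),
            _record(day=2, energy=1200.0, dairy=253.0),
            _record(day=3, energy=1400.0, dairy=250.0),
        ]
        dv = average_and_densify(recs)
        # mean amount 217.666..., mean energy 1200 -> 181.3888... g/1000 kcal
        assert dv.mean_energy == pytest.approx(1200.0)
        assert dv.densities["dairy"] == pytest.approx(653.0 / 3 / 1200 * 1000, rel=1e-12)
        assert dv.densities["dairy"] == pytest.approx(181.39, abs=0.005)

    def test_zero_energy_is_degenerate(self):
        with pytest.raises(DegenerateIntakeError):
            average_and_densify([_record(energy=0.0, dairy=10.0)])

    def test_missing_components_flagged_as_zero(self):
        dv = average_and_densify([_record(energy=1000.0, dairy=100.0)],
                                 components=["dairy", "fruits"])
        assert dv.densities["fruits"] == 0.0
        assert dv.missing_components == ("fruits",)

    def test_mixed_subjects_rejected(self):
        with pytest.raises(ValueError):
            average_and_densify([_record("a"), _record("b")])


class TestSubjectScoring:
    def test_all_max_criteria_gives_90(self, standard):
        profile, records = generate_targeted_subject(5, MAX_SCORE_DENSITIES_OLD)
        result = score_subject(profile, records, standard)
        assert result.total == pytest.approx(90.0, abs=1e-9)

    def test_zero_consumption_gives_5(self, standard):
        """Adequacy and moderation all score 0 at zero intake; the snack
        limitation component alone contributes its full 5 points."""
        profile, records = generate_targeted_subject(3, {})
        result = score_subject(profile, records, standard)
        assert result.total == pytest.approx(5.0, abs=1e-12)
        assert len(result.missing_components) == 11

    def test_worked_examples_embedded_in_one_subject(self, standard):
        densities = dict(MAX_SCORE_DENSITIES_OLD, dairy=200, snacks=45)
        profile, records = generate_targeted_subject(4, densities)
        result = score_subject(profile, records, standard)
        assert result.subscore("dairy") == pytest.approx(8.0, abs=1e-9)
        assert result.subscore("snacks") == pytest.approx(2.75, abs=1e-9)
        assert result.total == pytest.approx(90 - 2 - 2.25, abs=1e-9)

    def test_total_is_sum_of_subscores(self, standard):
        profile, records = generate_targeted_subject(2, {"dairy": 100, "cereals": 80})
        result = score_subject(profile, records, standard)
        assert result.total == pytest.approx(
            sum(cs.score for cs in result.component_scores), abs=1e-12
        )

    def test_unknown_components_ignored_but_reported(self, standard):
        profile, records = generate_targeted_subject(4, {"dairy": 100, "tofu_ice_cream": 50})
        result = score_subject(profile, records, standard)
        assert result.unknown_components == ("tofu_ice_cream",)
        assert len(result.component_scores) == 11


class TestCohortScoring:
    def test_empty_cohort(self, standard):
        results, rejects = score_cohort([], [], standard)
        assert results == [] and rejects == []

    def test_two_valid_subjects_sorted(self, standard):
        p1, r1 = generate_targeted_subject(3, {"dairy": 100}, subject_id="b")
        p2, r2 = generate_targeted_subject(4, {"dairy": 100}, subject_id="a")
        results, rejects = score_cohort([p1, p2], r1 + r2, standard)
        assert [r.subject_id for r in results] == ["a", "b"]
        assert not rejects

    def test_out_of_range_age_becomes_reject(self, standard):
        p1, r1 = generate_targeted_subject(3, {"dairy": 100}, subject_id="ok")
        p2, r2 = generate_targeted_subject(7, {"dairy": 100}, subject_id="too_old")
        results, rejects = score_cohort([p1, p2], r1 + r2, standard)
        assert [r.subject_id for r in results] == ["ok"]
        assert [(r.subject_id, r.reason) for r in rejects] == [("too_old", "age_out_of_range")]

    def test_orphan_records_listed(self, standard):
        p1, r1 = generate_targeted_subject(3, {"dairy": 100}, subject_id="known")
        _, r2 = generate_targeted_subject(3, {"dairy": 100}, subject_id="ghost")
        results, rejects = score_cohort([p1], r1 + r2, standard)
        assert [r.subject_id for r in results] == ["known"]
        assert [(r.subject_id, r.reason) for r in rejects] == [("ghost", "orphan_records")]


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    scale=st.floats(min_value=1e-3, max_value=1e3, allow_nan=False, allow_infinity=False),
    age=st.integers(min_value=2, max_value=5),
    seed=st.integers(min_value=0, max_value=2**16),
)
def test_density_invariance_under_energy_rescaling(standard, scale, age, seed):
    """Multiplying all amounts and energies by c > 0 leaves every subscore
    and the total unchanged: scoring depends on densities only."""
    rng = np.random.default_rng(seed)
    base_energy = float(rng.uniform(800, 1600))
    densities = {cid: float(rng.uniform(0, 3) * TABLE_CUTOFFS[cid][1] * 10)
                 for cid in standard.component_ids}
    profile, records = generate_targeted_subject(age, densities, energy_kcal=base_energy)
    scaled = [
        DailyIntakeRecord(r.subject_id, r.day, r.energy_kcal * scale,
                          {k: v * scale for k, v in r.amounts.items()})
        for r in records
    ]
    base = score_subject(profile, records, standard)
    res = score_subject(profile, scaled, standard)
    for a, b in zip(base.component_scores, res.component_scores):
        assert b.score == pytest.approx(a.score, abs=1e-9)
    assert res.total == pytest.approx(base.total, abs=1e-9)
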