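import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plantshift.errors import UnknownFoodError, ValidationError
from plantshift.food_composition import IAA_KEYS, AminoAcidVector
from plantshift.protein_quality import (
    OCCASIONS,
    ConsumptionEvent,
    Participant,
    daily_protein,
    occasion_amino_acids,
    score_consumption,
    similarity_factor,
)
from tests.conftest import make_profile

REL = 1e-9


def triple_loop_occasion(events, db, digested):
    """Independent per-event, per-AA scalar-loop oracle."""
    totals = {k: 0.0 for k in list(IAA_KEYS) + ["disp"]}
    for ev in events:
        item = db[ev.food_id]
        factor = db.digestibility[item.food_group] if digested else 1.0
        for k in IAA_KEYS:
            totals[k] += ev.amount_g / 100.0 * item.aa_profile.iaa_mg(k) * factor
        totals["disp"] += ev.amount_g / 100.0 * item.aa_profile.dispensable_aa_mg * factor
    return totals


def random_meal(db, rng, max_items=5):
    ids = [it.food_id for it in db]
    n = int(rng.integers(1, max_items + 1))
    return [
        ConsumptionEvent("p1", 1, "lunch", ids[int(rng.integers(len(ids)))],
                         float(rng.uniform(0.0, 300.0)))
        for _ in range(n)
    ]


class TestOccasionAminoAcids:
    def test_empty_event_list_gives_zero_vector(self, small_db):
        assert occasion_amino_acids([], small_db, digested=True).total_mg == 0.0

    def test_single_event_digestibility_arithmetic(self, pattern):
        # 200 g of a food with 500 mg lysine per 100 g at digestibility 0.8
        from plantshift.food_composition import (
            DigestibilityTable, FoodDatabase, FoodItem,
        )
        item = FoodItem("f", "f", "g",
                        AminoAcidVector(lys_mg=500.0, dispensable_aa_mg=1500.0))
        db = FoodDatabase([item], DigestibilityTable({"g": 0.8}))
        ev = ConsumptionEvent("p", 1, "dinner", "f", 200.0)
        vec = occasion_amino_acids([ev], db, digested=True)
        assert vec.lys_mg == pytest.approx(800.0)
        raw = occasion_amino_acids([ev], db, digested=False)
        assert raw.lys_mg == pytest.approx(1000.0)

    def test_unknown_food_id_is_named(self, small_db):
        ev = ConsumptionEvent("p", 1, "lunch", "no_such_food", 10.0)
        with pytest.raises(UnknownFoodError, match="no_such_food"):
            occasion_amino_acids([ev], small_db, digested=False)

    def test_matches_triple_loop_oracle(self, small_db, rng):
        for _ in range(50):
            meal = random_meal(small_db, rng)
            for digested in (False, True):
                vec = occasion_amino_acids(meal, small_db, digested)
                oracle = triple_loop_occasion(meal, small_db, digested)
                for k in IAA_KEYS:
                    assert vec.iaa_mg(k) == pytest.approx(oracle[k], rel=REL, abs=1e-12)
                assert vec.dispensable_aa_mg == pytest.approx(
                    oracle["disp"], rel=REL, abs=1e-12
                )


class TestSimilarityFactor:
    def test_pattern_matching_meal_scores_one(self, pattern):
        # exactly the pattern per g protein: no limiting amino acid, cap binds
        vec = make_profile({k: 1.0 for k in IAA_KEYS}, 10.0, pattern)
        assert similarity_factor(vec, pattern) == 1.0

    def test_limiting_lysine_ratio(self, pattern):
        # 10 g protein with 300 mg lysine -> 30 mg/g vs required 45 mg/g
        per_g = {k: 1.5 * pattern[k] for k in IAA_KEYS}
        per_g["lys"] = 30.0
        iaa_sum = sum(per_g.values())
        vec = AminoAcidVector(
            **{f"{k}_mg": per_g[k] * 10.0 for k in IAA_KEYS},
            dispensable_aa_mg=(1000.0 - iaa_sum) * 10.0,
        )
        assert similarity_factor(vec, pattern) == pytest.approx(30.0 / 45.0, rel=REL)
        # per-IAA loop cross-check
        protein = vec.protein_g
        loop = min(
            min((vec.iaa_mg(k) / protein) / pattern[k] for k in IAA_KEYS), 1.0
        )
        assert similarity_factor(vec, pattern) == pytest.approx(loop, rel=REL)

    def test_zero_protein_occasion_scores_one(self, pattern):
        assert similarity_factor(AminoAcidVector(), pattern) == 1.0

    @given(scale=st.floats(min_value=1e-3, max_value=1e3, allow_nan=False))
    @settings(deadline=None, max_examples=40)
    def test_scale_invariance(self, pattern, scale):
        vec = make_profile({"lys": 0.6}, 10.0, pattern)
        sf = similarity_factor(vec, pattern)
        assert similarity_factor(vec.scaled(scale), pattern) == pytest.approx(
            sf, rel=1e-9
        )


@pytest.fixture()
def participant():
    return Participant("p1", "male", 70.0, 80.0, 1.0)


class TestDailyProtein:
    def test_single_occasion_day_reduces_to_that_occasion(
        self, small_db, pattern, participant
    ):
        events = [ConsumptionEvent("p1", 1, "dinner", "beef", 150.0)]
        day = daily_protein(participant, events, small_db, pattern)
        dinner = next(o for o in day.occasions if o.occasion == "dinner")
        assert day.total_protein_g == pytest.approx(dinner.total_protein_g)
        assert day.utilizable_protein_g == pytest.approx(dinner.utilizable_protein_g)
        assert day.total_per_kg == pytest.approx(day.total_protein_g / 80.0)
        assert len(day.occasions) == len(OCCASIONS)

    def test_ordering_invariant_on_random_days(self, small_db, pattern, rng):
        p = Participant("p1", "female", 68.0, 65.0)
        for _ in range(30):
            events = []
            for occ in OCCASIONS:
                if rng.random() < 0.7:
                    events += [
                        ConsumptionEvent("p1", 1, occ, ev.food_id, ev.amount_g)
                        for ev in random_meal(small_db, rng, max_items=3)
                    ]
            day = daily_protein(p, events, small_db, pattern)
            tol = 1e-9 * max(1.0, day.total_protein_g)
            assert day.utilizable_protein_g <= day.digestible_protein_g + tol
            assert day.digestible_protein_g <= day.total_protein_g + tol
            for occ in day.occasions:
                assert occ.utilizable_protein_g == pytest.approx(
                    occ.similarity_factor * occ.digestible_protein_g, rel=1e-9
                )

    def test_per_meal_scoring_never_beats_whole_day_pooling(
        self, small_db, pattern, participant
    ):
        # lysine-poor breakfast plus lysine-rich dinner: pooling the whole day
        # lets bread borrow lysine from beef, so the per-occasion (strict
        # timeframe) utilizable protein must come out lower
        events = [
            ConsumptionEvent("p1", 1, "breakfast", "bread", 120.0),
            ConsumptionEvent("p1", 1, "dinner", "beef", 200.0),
        ]
        day = daily_protein(participant, events, small_db, pattern)
        pooled = occasion_amino_acids(events, small_db, digested=True)
        pooled_util = similarity_factor(pooled, pattern) * pooled.protein_g
        assert day.utilizable_protein_g < pooled_util

    def test_rejects_foreign_events(self, small_db, pattern, participant):
        with pytest.raises(ValidationError):
            daily_protein(
                participant,
                [ConsumptionEvent("other", 1, "lunch", "beef", 10.0)],
                small_db,
                pattern,
            )

    def test_homogeneity_in_amounts(self, small_db, pattern, participant, rng):
        events = [
            ConsumptionEvent("p1", 1, "lunch", ev.food_id, ev.amount_g)
            for ev in random_meal(small_db, rng)
        ]
        scaled = [
            ConsumptionEvent("p1", 1, "lunch", ev.food_id, 3.0 * ev.amount_g)
            for ev in events
        ]
        d1 = daily_protein(participant, events, small_db, pattern)
        d3 = daily_protein(participant, scaled, small_db, pattern)
        assert d3.total_protein_g == pytest.approx(3.0 * d1.total_protein_g, rel=1e-9)
        assert d3.utilizable_protein_g == pytest.approx(
            3.0 * d1.utilizable_protein_g, rel=1e-9
        )
        lunches = [
            next(o for o in d.occasions if o.occasion == "lunch") for d in (d1, d3)
        ]
        assert lunches[0].similarity_factor == pytest.approx(
            lunches[1].similarity_factor, rel=1e-9
        )


class TestScoreConsumptionFrame:
    def test_agrees_with_object_api(self, small_db, pattern, rng):
        # the vectorised frame path must match daily_protein event by event
        rows, expected = [], {}
        participants = pd.DataFrame(
            {
                "participant_id": ["a", "b"],
                "sex": ["male", "female"],
                "age": [70, 72],
                "body_weight_kg": [85.0, 70.0],
                "survey_weight": [1.0, 1.2],
            }
        )
        for pid, bw in (("a", 85.0), ("b", 70.0)):
            for day in (1, 2):
                events = []
                for occ in ("breakfast", "dinner"):
                    events += [
                        ConsumptionEvent(pid, day, occ, ev.food_id, ev.amount_g)
                        for ev in random_meal(small_db, rng, max_items=3)
                    ]
                p = Participant(pid, "male", 70.0, bw)
                expected[(pid, day)] = daily_protein(p, events, small_db, pattern)
                rows += [
                    {
                        "participant_id": pid, "day": day, "occasion": e.occasion,
                        "food_id": e.food_id, "amount_g": e.amount_g,
                    }
                    for e in events
                ]
        occ_df, daily_df = score_consumption(
            pd.DataFrame(rows), participants, small_db, pattern
        )
        for rec in daily_df.to_dict("records"):
            ref = expected[(rec["participant_id"], rec["day"])]
            assert rec["total_protein_g"] == pytest.approx(ref.total_protein_g, rel=REL)
            assert rec["utilizable_protein_g"] == pytest.approx(
                ref.utilizable_protein_g, rel=REL
            )
        assert (occ_df["similarity_factor"] <= 1.0 + 1e-12).all()
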