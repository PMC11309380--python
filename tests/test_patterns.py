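import numpy as np
import pytest

from azapick import (
    MODEL_IDS,
    Pattern,
    boost_predictions,
    decide_pick,
    enumerate_patterns,
    match,
    mine_patterns,
    sensitivity_curve,
)
from azapick.errors import InvalidArgumentError

from ._oracles import brute_mine
from .conftest import make_table, random_tables


class TestEnumerate:
    @pytest.mark.parametrize("k,expected", [(1, 2), (2, 8), (4, 80)])
    def test_small_counts(self, k, expected):
        pats = enumerate_patterns(MODEL_IDS[:k])
        assert len(pats) == expected
        assert len({(p.members, p.assigned) for p in pats}) == expected

    def test_full_count_is_3_pow_10_minus_1(self):
        pats = enumerate_patterns(MODEL_IDS)
        assert len(pats) == 59048
        assert len({(p.members, p.assigned) for p in pats}) == 59048

    def test_duplicate_ids_rejected(self):
        with pytest.raises(InvalidArgumentError):
            enumerate_patterns(("A_f", "A_f"))


class TestMatch:
    def test_singleton(self):
        p = Pattern(("A_f",), ("low",))
        assert match(p, {"pred_A_f": "low"})
        assert not match(p, {"pred_A_f": "high"})

    def test_conjunction(self):
        p = Pattern(("D_f", "S_l"), ("high", "low"))
        assert not p.matches({"pred_D_f": "high", "pred_S_l": "high"})
        assert p.matches({"pred_D_f": "high", "pred_S_l": "low"})

    def test_missing_prediction_rejected(self):
        with pytest.raises(InvalidArgumentError):
            Pattern(("A_f", "D_f"), ("low", "low")).matches({"pred_A_f": "low"})

    def test_agrees_with_elementwise_oracle(self, rng):
        ids = MODEL_IDS[:5]
        pats = enumerate_patterns(ids)
        for _ in range(50):
            row = {f"pred_{m}": rng.choice(["low", "high"]) for m in ids}
            p = pats[rng.integers(len(pats))]
            expected = all(row[f"pred_{m}"] == c for m, c in zip(p.members, p.assigned))
            assert p.matches(row) == expected

    def test_adding_member_never_increases_matches(self, rng):
        ids = MODEL_IDS[:4]
        tables = random_tables(rng, ids, n_shuffles=1, n_rows=40)
        rows = tables[0].to_dict("records")
        for _ in range(30):
            k = int(rng.integers(1, 4))
            members = tuple(rng.choice(ids, size=k, replace=False))
            assigned = tuple(rng.choice(["low", "high"], size=k))
            extra = rng.choice([m for m in ids if m not in members])
            bigger = Pattern(members + (extra,), assigned + (rng.choice(["low", "high"]),))
            small = Pattern(members, assigned)
            n_small = sum(small.matches(r) for r in rows)
            n_big = sum(bigger.matches(r) for r in rows)
            assert n_big <= n_small


class TestMinePatterns:
    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        ids = MODEL_IDS[:3]
        for _ in range(25):
            n_shuffles = int(rng.integers(1, 4))
            tables = random_tables(rng, ids, n_shuffles, n_rows=int(rng.integers(3, 30)))
            result = mine_patterns(tables, min_support_shuffles=1, model_ids=ids)
            expected = brute_mine(tables, ids, min_support=1)
            got = {
                (p.members, p.assigned): (p.implied_A_class, int(s))
                for p, s in zip(result.patterns, result.support)
            }
            assert got == expected

    def test_planted_rule_recovered_with_full_support(self, rng):
        from azapick import PlantedRule, run_experiment
        from azapick.crossval import ExperimentConfig

        cfg = ExperimentConfig(
            n_samples=600, n_shuffles=4, min_support_shuffles=4,
            planted_rules=[PlantedRule(("D_f", "S_f"), ("high", "high"), "high")],
        )
        res = run_experiment(cfg, seed=5)
        planted = [
            p for p in res.mining.patterns
            if p.members == ("D_f", "S_f") and p.assigned == ("high", "high")
        ]
        assert len(planted) == 1
        assert planted[0].implied_A_class == "high"
        idx = res.mining.patterns.index(planted[0])
        assert res.mining.support[idx] == 4

    def test_mixed_class_pattern_excluded(self):
        ids = MODEL_IDS[:2]
        table = make_table(
            [["high", "high"]] * 4, ["low", "low", "low", "high"], ids
        )
        result = mine_patterns([table], model_ids=ids)
        names = {(p.members, p.assigned) for p in result.patterns}
        assert (("A_f", "D_f"), ("high", "high")) not in names
        assert (("A_f",), ("high",)) not in names

    def test_direction_must_be_consistent_across_shuffles(self):
        ids = MODEL_IDS[:1]
        t1 = make_table([["high"], ["low"]], ["high", "low"], ids)
        t2 = make_table([["high"], ["low"]], ["low", "high"], ids)  # flipped direction
        result = mine_patterns([t1, t2], model_ids=ids)
        assert result.patterns == []

    def test_perfect_predictors_yield_single_model_patterns(self, perfect_table, labels):
        result = mine_patterns([perfect_table], labels)
        by_id = {(p.members, p.assigned): p for p in result.patterns}
        low = by_id[(("A_f",), ("low",))]
        high = by_id[(("A_f",), ("high",))]
        assert low.implied_A_class == "low" and high.implied_A_class == "high"
        ev = result.evaluations
        assert (ev.loc[ev["pattern"] == "A_f:low", "sensitivity"] == 100.0).all()

    def test_bad_min_support_rejected(self, perfect_table):
        with pytest.raises(InvalidArgumentError):
            mine_patterns([perfect_table], min_support_shuffles=2)


class TestSensitivityCurve:
    def test_counts_nondecreasing_as_support_drops(self, rng):
        tables = random_tables(rng, MODEL_IDS[:4], n_shuffles=5, n_rows=25)
        result = mine_patterns(tables, model_ids=MODEL_IDS[:4])
        curve = sensitivity_curve(result)
        assert list(curve["min_support"]) == [5, 4, 3, 2, 1]
        for col in ("n_patterns_low", "n_patterns_high"):
            assert (np.diff(curve[col]) >= 0).all()

    def test_perfect_predictors_give_100_everywhere(self, perfect_table, labels):
        result = mine_patterns([perfect_table], labels)
        curve = sensitivity_curve(result)
        assert (curve["mean_sensitivity_low"] == 100.0).all()
        assert (curve["mean_sensitivity_high"] == 100.0).all()

    def test_union_coverage_tracks_planted_fraction(self):
        """One planted antecedent covering a known fraction of one class."""
        ids = MODEL_IDS[:3]
        rng = np.random.default_rng(17)
        tables = []
        frac = 0.4
        for _ in range(3):
            n = 200
            truth = np.where(rng.random(n) < 0.5, "high", "low")
            rows = []
            for t in truth:
                if t == "high" and rng.random() < frac:
                    rows.append(["high", "high", "high"])
                else:
                    # keep D_f low so only the planted triple matches high
                    rows.append([rng.choice(["low", "high"]), "low",
                                 rng.choice(["low", "high"])])
            tables.append(make_table(rows, truth, ids))
        result = mine_patterns(tables, model_ids=ids)
        curve = sensitivity_curve(result)
        top = curve[curve["min_support"] == 3].iloc[0]
        assert top["mean_sensitivity_high"] == pytest.approx(100 * frac, abs=8)


class TestBoostAndDecide:
    LOW = Pattern(("D_f",), ("low",), "low")
    HIGH = Pattern(("S_f",), ("high",), "high")

    def test_agreeing_patterns_predict(self):
        assert boost_predictions({"pred_D_f": "low", "pred_S_f": "low"}, [self.LOW, self.HIGH]) == "low"
        assert boost_predictions({"pred_D_f": "high", "pred_S_f": "high"}, [self.LOW, self.HIGH]) == "high"

    def test_disagreeing_patterns_conflict(self):
        out = boost_predictions({"pred_D_f": "low", "pred_S_f": "high"}, [self.LOW, self.HIGH])
        assert out == "conflict"

    def test_no_match_abstains(self):
        assert boost_predictions({"pred_D_f": "high", "pred_S_f": "low"}, [self.LOW, self.HIGH]) == "abstain"

    def test_unmined_pattern_rejected(self):
        with pytest.raises(InvalidArgumentError):
            boost_predictions({"pred_D_f": "low"}, [Pattern(("D_f",), ("low",))])

    def test_pick_rules(self):
        assert decide_pick("high", "low").decision == "Pick"
        assert decide_pick("low", "high").decision == "Do not Pick"
        d = decide_pick("abstain", "low")
        assert d.decision == "Do not Pick" and d.used_fallback and not d.conflict
        d = decide_pick("conflict", "high")
        assert d.decision == "Pick" and d.conflict


class TestBoostBits:
    def test_vectorised_boost_agrees_with_row_boost(self, rng):
        from azapick import encode_predictions

        ids = MODEL_IDS[:4]
        tables = random_tables(rng, ids, n_shuffles=3, n_rows=30)
        result = mine_patterns(tables, model_ids=ids)
        probe = random_tables(rng, ids, n_shuffles=1, n_rows=50)[0]
        bits = encode_predictions(probe, ids)
        fast = result.boost_bits(bits, min_support=2)
        kept = [p for p, s in zip(result.patterns, result.support) if s >= 2]
        slow = [boost_predictions(row, kept) for row in probe.to_dict("records")]
        assert list(fast) == slow
        from azapick.patterns import boost_many

        assert list(boost_many(probe, kept, ids)) == slow
        assert [p.name() for p in result.filtered(2).patterns] == [p.name() for p in kept]
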