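"""Fisher right-tail ORA, permutation null, direction composition."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from btwas.enrich import (
    GeneSetCollection,
    direction_composition,
    fisher_right_tail,
    permutation_fdr,
    permutation_rank_agreement,
    run_ora,
    table2_report,
)


def hypergeom_tail_enumeration(x, K, n, N):
    """Independent oracle: sum the hypergeometric pmf from x upward."""
    total = comb(N, n)
    return sum(
        comb(K, k) * comb(N - K, n - k) for k in range(x, min(K, n) + 1)
    ) / total


class TestFisher:
    def test_zero_overlap_is_one(self):
        assert fisher_right_tail(0, 5, 4, 10) == 1.0

    def test_enumerated_small_cases(self):
        assert fisher_right_tail(4, 5, 4, 10) == pytest.approx(5 / 210,
                                                               abs=1e-12)
        assert fisher_right_tail(2, 2, 2, 4) == pytest.approx(1 / 6,
                                                              abs=1e-12)

    def test_matches_enumeration_on_sampled_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            N = int(rng.integers(2, 26))
            n = int(rng.integers(1, N + 1))
            K = int(rng.integers(1, N + 1))
            x = int(rng.integers(0, min(K, n) + 1))
            assert fisher_right_tail(x, K, n, N) == pytest.approx(
                hypergeom_tail_enumeration(x, K, n, N), abs=1e-10
            )

    def test_monotone_decreasing_in_overlap(self):
        ps = [fisher_right_tail(x, 8, 10, 40) for x in range(9)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_bounds_violations_rejected(self):
        with pytest.raises(ValueError):
            fisher_right_tail(5, 4, 10, 20)
        with pytest.raises(ValueError):
            fisher_right_tail(1, 4, 30, 20)


@pytest.fixture()
def toy_collection():
    sets = {
        "disjoint": frozenset({"g8", "g9"}),
        "hit": frozenset({"g0", "g1", "g2"}),
        "half": frozenset({"g0", "g5", "g6", "g7"}),
    }
    universe = frozenset(f"g{i}" for i in range(10))
    return GeneSetCollection(sets=sets, universe=universe)


class TestRunOra:
    def test_disjoint_set_has_unit_p(self, toy_collection):
        ora = run_ora({"all": ["g0", "g1", "g2"]}, toy_collection)
        rec = ora.loc[("disjoint", "all")]
        assert rec["x"] == 0 and rec["p"] == 1.0

    def test_full_universe_input_degenerate(self, toy_collection):
        ora = run_ora({"all": [f"g{i}" for i in range(10)]}, toy_collection)
        for name in toy_collection.sets:
            rec = ora.loc[(name, "all")]
            assert rec["x"] == rec["K"]
            assert rec["p"] == 1.0
            assert rec["degenerate"]

    def test_empty_stratum_not_applicable(self, toy_collection):
        ora = run_ora({"all": ["g0"], "negative": []}, toy_collection)
        rec = ora.loc[("hit", "negative")]
        assert rec["not_applicable"]
        assert np.isnan(rec["p"])

    def test_ratio_and_q_within_stratum(self, toy_collection):
        ora = run_ora({"all": ["g0", "g1", "g2"]}, toy_collection)
        rec = ora.loc[("hit", "all")]
        assert rec["ratio"] == pytest.approx(1.0)
        sub = ora.xs("all", level="stratum")
        assert (sub["q"] >= sub["p"] - 1e-15).all()

    def test_null_input_false_positive_rate_conservative(self):
        """Uniform random input lists: the p < 0.05 rate is at most ~5%
        (the discrete test is conservative) and not degenerate."""
        rng = np.random.default_rng(12)
        universe = frozenset(f"g{i}" for i in range(400))
        genes = sorted(universe)
        sets = {
            f"S{j}": frozenset(rng.choice(genes, size=25, replace=False))
            for j in range(40)
        }
        coll = GeneSetCollection(sets=sets, universe=universe)
        hits, trials = 0, 0
        for rep in range(25):
            inp = rng.choice(genes, size=60, replace=False)
            ora = run_ora({"all": list(inp)}, coll)
            hits += int((ora["p"] < 0.05).sum())
            trials += len(ora)
        rate = hits / trials
        mc_se = np.sqrt(0.05 * 0.95 / trials)
        assert 0.01 <= rate <= 0.05 + 2 * mc_se


class TestPermutation:
    def test_add_one_floor_and_determinism(self, toy_collection):
        ora = run_ora({"all": ["g0", "g1", "g2"]}, toy_collection)
        out1 = permutation_fdr(ora, toy_collection, n_input=3, B=200, seed=5)
        out2 = permutation_fdr(ora, toy_collection, n_input=3, B=200, seed=5)
        pd.testing.assert_frame_equal(out1, out2)
        fdrs = out1.xs("all", level="stratum")["permutation_fdr"]
        assert (fdrs >= 1 / 201).all()

    def test_universe_sized_set_has_fdr_one(self):
        universe = frozenset(f"g{i}" for i in range(12))
        coll = GeneSetCollection(
            sets={"everything": universe}, universe=universe
        )
        ora = run_ora({"all": ["g0", "g1", "g2"]}, coll)
        out = permutation_fdr(ora, coll, n_input=3, B=150, seed=1)
        assert out.loc[("everything", "all"), "permutation_fdr"] == (
            pytest.approx(1.0)
        )

    def test_small_b_rejected(self, toy_collection):
        ora = run_ora({"all": ["g0"]}, toy_collection)
        with pytest.raises(ValueError):
            permutation_fdr(ora, toy_collection, n_input=1, B=50, seed=0)


class TestDirectionComposition:
    def test_all_positive_set(self, toy_collection):
        directions = pd.Series(
            {"g0": "positive", "g1": "positive", "g2": "positive"}
        )
        assert direction_composition("hit", toy_collection, directions) == (
            (1.0, 0.0, 0.0)
        )

    def test_seven_of_seven_positive(self):
        universe = frozenset(f"g{i}" for i in range(50))
        coll = GeneSetCollection(
            sets={"heme": frozenset(f"g{i}" for i in range(7))},
            universe=universe,
        )
        directions = pd.Series({f"g{i}": "positive" for i in range(7)})
        pos, neg, ns = direction_composition("heme", coll, directions)
        assert (pos, neg, ns) == (1.0, 0.0, 0.0)

    def test_fractions_partition_to_one(self, toy_collection):
        directions = pd.Series({"g0": "positive", "g5": "negative"})
        pos, neg, ns = direction_composition("half", toy_collection,
                                             directions)
        assert pos + neg + ns == pytest.approx(1.0, abs=1e-12)

    def test_unknown_set_rejected(self, toy_collection):
        with pytest.raises(KeyError):
            direction_composition("nope", toy_collection, pd.Series(dtype=object))


def test_gmt_round_trip(tmp_path, toy_collection):
    path = tmp_path / "sets.gmt"
    toy_collection.to_gmt(path)
    back = GeneSetCollection.from_gmt(path)
    assert back.sets == toy_collection.sets


def test_table2_report_na_convention(toy_collection):
    ora = run_ora(
        {"all": ["g0", "g1"], "positive": ["g0", "g1"], "negative": []},
        toy_collection,
    )
    directions = pd.Series({"g0": "positive", "g1": "positive"})
    rep = table2_report(ora, toy_collection, directions)
    assert rep.loc["hit", "fdr_negative"] == "N. A."
    assert rep.loc["hit", "genes_all"] == 2
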