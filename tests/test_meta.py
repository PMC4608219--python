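"""z-conversion, Stouffer combination, BH FDR, gene collapsing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from btwas.meta import (
    bh_adjust,
    collapse_genes,
    combine_cohorts,
    direction_summary,
    stouffer,
    summary_from_counts,
    z_from_p_beta,
)


class TestZConversion:
    def test_inverse_normal_at_p05(self):
        assert z_from_p_beta(0.05, 1.0) == pytest.approx(1.959964, abs=1e-6)

    def test_p_one_maps_to_zero(self):
        assert z_from_p_beta(1.0, 2.0) == pytest.approx(0.0, abs=1e-12)

    def test_sign_symmetry(self):
        assert z_from_p_beta(0.05, -1.0) == pytest.approx(-1.959964, abs=1e-6)

    def test_p_zero_rejected(self):
        with pytest.raises(ValueError):
            z_from_p_beta(0.0, 1.0)


class TestStouffer:
    def test_equal_inputs_accumulate_evidence(self):
        # two cohorts at z = 2 combine to sqrt(2) * 2 under sqrt(n) weights
        z, _ = stouffer([2.0, 2.0], [100, 100])
        assert z == pytest.approx(2.0 * np.sqrt(2.0), abs=1e-12)

    def test_cancellation(self):
        z, p = stouffer([2.0, -2.0], [100, 100])
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_weighted_combination_formula(self):
        z, _ = stouffer([2.0, 3.0], [100, 400])
        assert z == pytest.approx((10 * 2 + 20 * 3) / np.sqrt(500), abs=1e-6)
        assert z == pytest.approx(3.57771, abs=1e-5)

    def test_single_cohort_reduces_to_its_z(self):
        z, _ = stouffer([1.7], [250])
        assert z == pytest.approx(1.7, abs=1e-12)

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError):
            stouffer([1.0], [0])


class TestBH:
    def test_single_p(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_hand_step_up(self):
        q = bh_adjust([0.001, 0.01, 0.03, 0.05])
        np.testing.assert_allclose(q, [0.004, 0.02, 0.04, 0.05], atol=1e-12)

    def test_all_equal_p(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2] * 3)

    def test_agrees_with_reference_step_up(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            p = rng.uniform(1e-8, 1.0, size=rng.integers(1, 200))
            _, q_ref, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(bh_adjust(p), q_ref, atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-10, 1.0), min_size=1, max_size=60))
    def test_q_at_least_p_and_sorted_monotone(self, p):
        p = np.asarray(p)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        assert (q <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def _meta_frame(rows):
    df = pd.DataFrame(rows).set_index("probe")
    return df


class TestCollapseGenes:
    def test_min_p_representative(self):
        meta = _meta_frame([
            dict(probe="P1", p_meta=0.01, q=0.005, z_meta=3.0),
            dict(probe="P2", p_meta=0.001, q=0.004, z_meta=4.0),
        ])
        ann = pd.Series({"P1": "G1", "P2": "G1"})
        out = collapse_genes(meta, ann)
        assert out.loc["G1", "probe"] == "P2"
        assert out.loc["G1", "direction_class"] == "positive"

    def test_discordant_significant_probes_are_inconsistent(self):
        meta = _meta_frame([
            dict(probe="P1", p_meta=0.001, q=0.004, z_meta=4.0),
            dict(probe="P2", p_meta=0.002, q=0.005, z_meta=-4.0),
        ])
        out = collapse_genes(meta, pd.Series({"P1": "G1", "P2": "G1"}))
        assert out.loc["G1", "direction_class"] == "inconsistent"

    def test_gene_without_significant_probe_absent(self):
        meta = _meta_frame([
            dict(probe="P1", p_meta=0.5, q=0.6, z_meta=0.5),
        ])
        out = collapse_genes(meta, pd.Series({"P1": "G1"}))
        assert "G1" not in out.index

    def test_tie_broken_by_smallest_probe_id(self):
        meta = _meta_frame([
            dict(probe="P9", p_meta=0.001, q=0.004, z_meta=4.0),
            dict(probe="P2", p_meta=0.001, q=0.004, z_meta=4.1),
        ])
        out = collapse_genes(meta, pd.Series({"P9": "G1", "P2": "G1"}))
        assert out.loc["G1", "probe"] == "P2"


class TestDirectionSummary:
    def test_published_meta_analysis_percentages(self):
        out = summary_from_counts(
            {"positive": 1269, "negative": 2411, "inconsistent": 82}
        )
        assert out.loc["positive", "percent"] == 33.7
        assert out.loc["negative", "percent"] == 64.1
        assert out.loc["inconsistent", "percent"] == 2.2

    def test_top_pathway_gene_percentages(self):
        out = summary_from_counts({"positive": 171, "negative": 225})
        assert out.loc["positive", "percent"] == 43.2
        assert out.loc["negative", "percent"] == 56.8
        assert out.loc["inconsistent", "percent"] == 0.0

    def test_single_gene(self):
        out = summary_from_counts({"positive": 1})
        assert out.loc["positive", "percent"] == 100.0
        assert out["count"].sum() == 1


class TestCombineCohorts:
    def test_single_cohort_meta_equals_cohort_z(self):
        df = pd.DataFrame(
            dict(probe=["P1", "P2"], cohort="A", beta=[0.1, -0.2],
                 se=[0.05, 0.05], t=[2.0, -4.0], p=[0.05, 0.001],
                 n=[100, 100])
        ).set_index("probe")
        meta = combine_cohorts([df])
        z1 = z_from_p_beta(0.05, 0.1)
        assert meta.loc["P1", "z_meta"] == pytest.approx(z1, abs=1e-10)
        assert meta.loc["P1", "n_total"] == 100

    def test_direction_recovery_no_inconsistent_genes(self, fitted):
        """With gene-wise planted signs, no significant gene is classified
        inconsistent."""
        results, truth = fitted
        assert (results.gene_results["direction_class"]
                != "inconsistent").all()
        # planted directions agree with recovered classes
        merged = results.gene_results.join(truth.genes, how="inner")
        planted = merged[merged["direction"].isin(["positive", "negative"])]
        assert (planted["direction_class"] == planted["direction"]).all()
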