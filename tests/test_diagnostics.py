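"""Probe-wise ANOVA, q-values, PCA, and signature scoring."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

import mcombat as mc
from mcombat.exceptions import ValidationError

from conftest import make_matrix

pvectors = st.lists(
    st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=2, max_size=200
)


def two_batch_design(n_per=3):
    ids = tuple(f"s{i}" for i in range(2 * n_per))
    return ids, mc.BatchDesign(ids, ("A",) * n_per + ("B",) * n_per)


class TestProbeAnova:
    def test_identical_groups_give_null_f(self):
        ids, design = two_batch_design(2)
        Y = mc.ExpressionMatrix([[0, 1, 0, 1]], ("g",), ids)
        res = mc.probe_anova(Y, design)
        assert res.f_statistic[0] == pytest.approx(0.0)
        assert res.p_values[0] == pytest.approx(1.0)

    def test_hand_computed_f_and_p(self):
        ids, design = two_batch_design(3)
        Y = mc.ExpressionMatrix([[1, 2, 3, 2, 3, 4]], ("g",), ids)
        res = mc.probe_anova(Y, design)
        assert res.f_statistic[0] == pytest.approx(1.5)  # SSB=1.5, SSW=4
        assert (res.df_between, res.df_within) == (1, 4)
        assert res.p_values[0] == pytest.approx(0.288, abs=1e-3)

    def test_degenerate_probes_flagged(self):
        ids, design = two_batch_design(2)
        Y = mc.ExpressionMatrix(
            [[1.0, 1.0, 2.0, 2.0], [3.0, 3.0, 3.0, 3.0]], ("sep", "const"), ids
        )
        res = mc.probe_anova(Y, design)
        assert res.flag[0] == "zero_within" and res.p_values[0] == 0.0
        assert res.flag[1] == "constant" and res.p_values[1] == 1.0

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(8)
        Y = make_matrix(rng.normal(8.0, 1.0, (10000, 30)))
        design = mc.BatchDesign(Y.sample_ids, ("A",) * 10 + ("B",) * 10 + ("C",) * 10)
        res = mc.probe_anova(Y, design)
        assert stats.kstest(res.p_values, "uniform").pvalue > 0.01
        assert abs((res.p_values < 0.05).mean() - 0.05) < 0.01


class TestQValues:
    @given(pvectors)
    def test_pi0_one_reduces_to_benjamini_hochberg(self, p):
        q, _ = mc.estimate_qvalues(p, pi0=1.0)
        np.testing.assert_array_equal(q, multipletests(p, method="fdr_bh")[1])

    def test_bh_step_up_by_hand(self):
        q, _ = mc.estimate_qvalues([0.01, 0.02, 0.03, 0.04], pi0=1.0)
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_null_simulation_pi0_near_one(self):
        rng = np.random.default_rng(12)
        pi0 = mc.estimate_pi0(rng.uniform(size=5000))
        assert 0.9 <= pi0 <= 1.0

    def test_few_pvalues_fall_back_to_pi0_one(self):
        with pytest.warns(UserWarning, match="unstable"):
            assert mc.estimate_pi0([0.2, 0.5, 0.9]) == 1.0

    def test_qvalues_monotone_in_pvalue_order(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(size=500)
        q, _ = mc.estimate_qvalues(p)
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()
        assert ((q >= 0) & (q <= 1)).all()

    @given(pvectors, st.floats(min_value=0.01, max_value=0.5),
           st.floats(min_value=0.5, max_value=0.99))
    def test_count_significant_monotone_in_threshold(self, p, lo, hi):
        q, _ = mc.estimate_qvalues(p, pi0=1.0)
        assert mc.count_significant(q, lo) <= mc.count_significant(q, hi)

    def test_count_significant_strict_threshold(self):
        assert mc.count_significant([0.005, 0.02], 0.01) == 1
        assert mc.count_significant([0.01], 0.01) == 0  # strict inequality


class TestPCA:
    def test_perfectly_correlated_probes_are_rank_one(self):
        Y = make_matrix([[1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0]])
        res = mc.top_variable_pca(Y, k=2, c=2)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)
        assert res.explained_variance_ratio[1] == pytest.approx(0.0, abs=1e-10)

    def test_top_k_selection_by_variance(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=6)
        Y = make_matrix(
            np.vstack([np.sqrt(v) * base for v in (3.0, 2.0, 1.0)]),
            probes=("big", "mid", "small"),
        )
        res = mc.top_variable_pca(Y, k=2, c=1)
        assert res.probe_ids == ("big", "mid")

    def test_k_larger_than_matrix_rejected(self):
        Y = make_matrix([[1.0, 2.0], [3.0, 5.0]])
        with pytest.raises(ValidationError, match="exceeds"):
            mc.top_variable_pca(Y, k=3)

    def test_spectrum_and_reconstruction(self):
        rng = np.random.default_rng(21)
        Y = make_matrix(rng.normal(8, 1, (15, 10)))
        c = 10
        res = mc.top_variable_pca(Y, k=15, c=c)
        ratio = res.explained_variance_ratio
        assert (np.diff(ratio) <= 1e-12).all()
        assert ratio.sum() <= 1.0 + 1e-12
        # scores of distinct components are orthogonal
        gram = res.scores.to_numpy().T @ res.scores.to_numpy()
        np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0.0, atol=1e-8)
        # full-rank reconstruction of the centered selected submatrix
        recon = res.scores.to_numpy() @ res.components + res.center
        sel = Y.to_frame().loc[list(res.probe_ids)].to_numpy().T
        np.testing.assert_allclose(recon, sel, atol=1e-8)

    def test_mcombat_shrinks_batch_centroid_spread(self, strong_sim):
        Y, design, _ = strong_sim
        adj = mc.mcombat(Y, design)
        def max_centroid_gap(mat):
            res = mc.top_variable_pca(mat, k=200, c=2)
            cent = res.batch_centroids(design).to_numpy()
            gaps = [
                np.linalg.norm(cent[i] - cent[j])
                for i in range(len(cent))
                for j in range(i + 1, len(cent))
            ]
            return max(gaps)
        assert max_centroid_gap(adj) < max_centroid_gap(Y)


class TestSignatures:
    def test_score_is_mean_up_minus_mean_down(self):
        Y = make_matrix([[2.0, 1.0], [4.0, 5.0], [1.0, 2.0], [3.0, 3.0]],
                        probes=("u1", "u2", "d1", "d2"))
        sig = mc.SignatureDefinition("s", ("u1", "u2"), ("d1", "d2"), cutoff=0.0)
        scores = mc.signature_score(Y, sig)
        assert scores.iloc[0] == pytest.approx(1.0)  # (2+4)/2 - (1+3)/2

    def test_constant_probe_shift_leaves_score_unchanged(self):
        rng = np.random.default_rng(5)
        Y = make_matrix(rng.normal(8, 1, (6, 4)),
                        probes=("u1", "u2", "u3", "d1", "d2", "d3"))
        sig = mc.SignatureDefinition("s", ("u1", "u2", "u3"), ("d1", "d2", "d3"))
        shifted = mc.ExpressionMatrix(Y.values + 7.5, Y.probe_ids, Y.sample_ids)
        np.testing.assert_allclose(
            mc.signature_score(Y, sig), mc.signature_score(shifted, sig), atol=1e-12
        )

    def test_missing_probes_listed(self):
        Y = make_matrix([[1.0, 2.0]], probes=("u1",))
        sig = mc.SignatureDefinition("s", ("u1",), ("nope",))
        with pytest.raises(ValidationError, match="nope"):
            mc.signature_score(Y, sig)

    def test_overlapping_lists_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            mc.SignatureDefinition("s", ("a", "b"), ("b",))

    def test_mcombat_aligns_batch_mean_scores_to_reference(self, strong_sim):
        Y, design, _ = strong_sim
        adj = mc.mcombat(Y, design)
        probes = list(Y.probe_ids)
        sig = mc.SignatureDefinition("s", tuple(probes[:20]), tuple(probes[20:40]))
        scores = mc.signature_score(adj, sig)
        ref_idx = design.batch_indices()[design.reference]
        ref_mean = mc.signature_score(Y, sig).iloc[ref_idx].mean()
        for label, idx in design.batch_indices().items():
            assert scores.iloc[idx].mean() == pytest.approx(ref_mean, abs=1e-6)

    def test_high_risk_proportion(self):
        assert mc.high_risk_proportion([-1.0, 0.0, 1.0], 0.0) == pytest.approx(1 / 3)
        assert mc.high_risk_proportion([0.5, 1.0], -2.0) == 1.0

    def test_high_risk_proportions_align_after_mcombat(self):
        # two batches identical up to an injected shift
        rng = np.random.default_rng(17)
        base = rng.normal(8, 1, (60, 40))
        shifted = np.hstack([base[:, :20], base[:, 20:] + 1.0])
        Y = make_matrix(shifted)
        design = mc.BatchDesign(Y.sample_ids, ("A",) * 20 + ("B",) * 20, reference="A")
        adj = mc.mcombat(Y, design)
        probes = list(Y.probe_ids)
        sig = mc.SignatureDefinition("s", tuple(probes[:15]), tuple(probes[15:30]))
        cutoff = float(np.median(mc.signature_score(Y, sig).iloc[:20]))
        props = [
            mc.high_risk_proportion(mc.signature_score(adj, sig).iloc[idx], cutoff)
            for idx in design.batch_indices().values()
        ]
        assert abs(props[0] - props[1]) < 0.35  # binomial noise at n=20
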