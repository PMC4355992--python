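"""End-to-end adjustment pipelines: anchoring, identities, invariances."""
import dataclasses

import numpy as np
import pytest

import mcombat as mc
from mcombat.exceptions import ValidationError

from conftest import make_matrix


class TestBacktransform:
    def test_identity_composition_with_trivial_posterior(self, strong_sim):
        # Forcing gamma* = 0, delta2* = 1 must make backtransform the exact
        # inverse of standardization.
        Y, design, _ = strong_sim
        fit = mc.fit_gene_models(Y, design, "pooled")
        Z = mc.standardize(Y, fit, design)
        est = mc.estimate_hyperparameters(mc.naive_batch_estimates(Z, design))
        est = dataclasses.replace(
            est,
            gamma_star=np.zeros_like(est.gamma_hat),
            delta2_star=np.ones_like(est.delta2_hat),
            n_iterations=np.zeros(design.n_batches, dtype=int),
        )
        out = mc.backtransform(Z, est, fit, design, "grand")
        np.testing.assert_allclose(out.values, Y.values, atol=1e-9)

    def test_anchor_mode_mismatch_rejected(self, toy):
        Y, design = toy
        fit = mc.fit_gene_models(Y, design, "pooled")
        Z = mc.standardize(Y, fit, design)
        est = mc.estimate_hyperparameters(mc.naive_batch_estimates(Z, design))
        est = dataclasses.replace(
            est,
            gamma_star=est.gamma_hat,
            delta2_star=est.delta2_hat,
            n_iterations=np.zeros(2, dtype=int),
        )
        with pytest.raises(ValidationError, match="batch-wise fit"):
            mc.backtransform(Z, est, fit, design, "reference")


class TestMCombat:
    def test_toy_maps_second_batch_onto_reference(self, toy):
        Y, design = toy
        out = mc.mcombat(Y, design)
        np.testing.assert_allclose(out.values[0, 3:], [1.0, 2.0, 3.0], atol=1e-10)
        np.testing.assert_allclose(out.values[:, :3], Y.values[:, :3], atol=1e-12)

    def test_reference_batch_is_exact_fixed_point(self, strong_sim):
        Y, design, _ = strong_sim
        out = mc.mcombat(Y, design)
        idx = design.batch_indices()[design.reference]
        assert np.abs(out.values[:, idx] - Y.values[:, idx]).max() < 1e-8

    def test_every_batch_inherits_reference_moments(self, strong_sim):
        Y, design, _ = strong_sim
        out = mc.mcombat(Y, design)
        ref_idx = design.batch_indices()[design.reference]
        ref_mean = Y.values[:, ref_idx].mean(axis=1)
        ref_sd = Y.values[:, ref_idx].std(axis=1, ddof=0)
        for label, idx in design.batch_indices().items():
            np.testing.assert_allclose(
                out.values[:, idx].mean(axis=1), ref_mean, atol=1e-6
            )
            np.testing.assert_allclose(
                out.values[:, idx].std(axis=1, ddof=0), ref_sd, atol=1e-6
            )

    def test_missing_reference_rejected(self, strong_sim):
        Y, design, _ = strong_sim
        bare = dataclasses.replace(design, reference=None)
        with pytest.raises(ValidationError, match="reference"):
            mc.mcombat(Y, bare)


class TestCombat:
    def test_single_batch_is_identity(self):
        rng = np.random.default_rng(9)
        Y = make_matrix(rng.normal(8, 1, (20, 12)))
        design = mc.BatchDesign(Y.sample_ids, ("A",) * 12)
        out = mc.combat(Y, design)
        assert np.abs(out.values - Y.values).max() < 1e-8

    def test_shape_and_index_preservation(self, strong_sim):
        Y, design, _ = strong_sim
        for out in (mc.combat(Y, design), mc.mcombat(Y, design)):
            assert out.probe_ids == Y.probe_ids
            assert out.sample_ids == Y.sample_ids
            assert out.values.shape == Y.values.shape

    def test_batch_means_equalized_across_batches(self, strong_sim):
        Y, design, _ = strong_sim
        out = mc.combat(Y, design)
        before_spread = np.ptp(
            [Y.values[:, i].mean(axis=1) for i in design.batch_indices().values()],
            axis=0,
        )
        after_spread = np.ptp(
            [out.values[:, i].mean(axis=1) for i in design.batch_indices().values()],
            axis=0,
        )
        assert np.median(after_spread) < 0.1 * np.median(before_spread)

    def test_batch_free_data_nearly_unchanged(self):
        cfg = mc.SimulationConfig(
            n_genes=400, batch_sizes=(30, 30, 30),
            gamma_bar=0.0, tau2=0.0, lam=None, theta=None, seed=3,
        )
        Y, design, truth = mc.simulate_dataset(cfg)
        out = mc.combat(Y, design)
        # residual change is O(sigma/sqrt(n)); generous multiple of that scale
        assert np.abs(out.values - Y.values).mean() < 0.15 * truth.sigma.mean()

    def test_column_permutation_equivariance(self, strong_sim):
        Y, design, _ = strong_sim
        rng = np.random.default_rng(4)
        perm = rng.permutation(Y.n_samples)
        Yp = mc.ExpressionMatrix(
            Y.values[:, perm],
            Y.probe_ids,
            tuple(Y.sample_ids[i] for i in perm),
        )
        dp = mc.BatchDesign(
            Yp.sample_ids,
            tuple(design.batch_labels_per_sample[i] for i in perm),
            reference=design.reference,
        )
        for fn in (mc.combat, mc.mcombat):
            out = fn(Y, design)
            outp = fn(Yp, dp)
            np.testing.assert_allclose(outp.values, out.values[:, perm], atol=1e-9)


class TestZeroVariancePolicy:
    def test_passthrough_copies_flat_probe_and_reports_it(self, strong_sim):
        Y, design, _ = strong_sim
        flat = np.full(Y.n_samples, 5.0)
        Y2 = mc.ExpressionMatrix(
            np.vstack([Y.values, flat]), Y.probe_ids + ("flat",), Y.sample_ids
        )
        out, report = mc.combat(Y2, design, return_report=True)
        np.testing.assert_array_equal(out.values[-1], flat)
        assert report.passthrough_probes == ["flat"]
        out2, report2 = mc.mcombat(Y2, design, return_report=True)
        np.testing.assert_array_equal(out2.values[-1], flat)
        assert report2.passthrough_probes == ["flat"]

    def test_error_policy_raises(self, strong_sim):
        Y, design, _ = strong_sim
        Y2 = mc.ExpressionMatrix(
            np.vstack([Y.values, np.full(Y.n_samples, 5.0)]),
            Y.probe_ids + ("flat",),
            Y.sample_ids,
        )
        with pytest.raises(ValidationError, match="flat"):
            mc.combat(Y2, design, zero_variance="error")

    def test_within_batch_flat_probe_passed_through_by_mcombat(self, toy):
        Y, design = toy
        # varies overall but is constant inside batch A
        row = np.array([2.0, 2.0, 2.0, 4.0, 5.0, 6.0])
        Y2 = mc.ExpressionMatrix(
            np.vstack([Y.values, row]), Y.probe_ids + ("halfflat",), Y.sample_ids
        )
        out, report = mc.mcombat(Y2, design, return_report=True)
        assert report.passthrough_probes == ["halfflat"]
        np.testing.assert_array_equal(out.values[-1], row)
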