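"""Prior covariance construction and the longitudinal mean structure."""

import numpy as np
import pytest

from btrr.model import (
    ModelConfig,
    ModelState,
    FamilyState,
    StudyData,
    build_correlation,
    build_families,
    build_margin_covariance,
    mean_tensor,
    prior_coefficient_covariance,
)
from btrr.tensor_core import CPTensor, VoxelGrid, reconstruct

from conftest import random_cp, tiny_study


class TestCorrelation:
    def test_alpha_zero_gives_all_ones(self):
        np.testing.assert_array_equal(build_correlation(0.0, 3), np.ones((3, 3)))

    def test_unit_alpha_two_points(self):
        lam = build_correlation(1.0, 2)
        assert lam[0, 0] == lam[1, 1] == 1.0
        assert lam[0, 1] == pytest.approx(np.exp(-1.0))

    def test_brute_force_and_psd(self):
        lam = build_correlation(2.0, 4)
        for k1 in range(4):
            for k2 in range(4):
                assert lam[k1, k2] == pytest.approx(np.exp(-2.0 * (k1 - k2) ** 2))
        assert np.min(np.linalg.eigvalsh(lam)) >= -1e-10

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            build_correlation(-0.1, 3)

    @pytest.mark.parametrize("w,alpha,p", [(1.0, 0.5, 5), (0.3, 3.0, 7), (2.0, 0.0, 4)])
    def test_margin_covariance_symmetric_psd(self, w, alpha, p):
        W = build_margin_covariance(w, alpha, p)
        np.testing.assert_allclose(W, W.T)
        assert np.min(np.linalg.eigvalsh(W)) >= -1e-10
        np.testing.assert_allclose(np.diag(W), w)


class TestMarginCovariance:
    def test_large_alpha_approaches_identity(self):
        W = build_margin_covariance(1.0, 50.0, 4)
        np.testing.assert_allclose(W, np.eye(4), atol=1e-20)

    def test_alpha_zero_constant_matrix(self):
        np.testing.assert_array_equal(
            build_margin_covariance(2.0, 0.0, 2), np.full((2, 2), 2.0)
        )

    def test_single_offdiagonal_element(self):
        W = build_margin_covariance(0.5, 1.0, 3)
        assert W[0, 2] == pytest.approx(0.5 * np.exp(-4.0))

    def test_nonpositive_w_rejected(self):
        with pytest.raises(ValueError):
            build_margin_covariance(0.0, 1.0, 3)

    def test_degenerate_extent_is_scalar_one(self):
        np.testing.assert_array_equal(build_correlation(2.0, 1), np.ones((1, 1)))


def _state_for(config, data, rng, rank=2, zero=False):
    fams = {}
    for fam in build_families(config, data):
        cp = (
            CPTensor.zeros(data.grid.dims, rank)
            if zero
            else random_cp(rng, data.grid.dims, rank)
        )
        fams[fam.key] = FamilyState(
            cp=cp,
            w=np.ones((3, rank)),
            lam=np.ones((3, rank)),
            alpha=np.ones((3, rank)),
            tau=1.0,
        )
    return ModelState(fams, sigma2=1.0)


class TestMeanTensor:
    def test_all_zero_coefficients(self, rng):
        data = tiny_study(rng)
        config = ModelConfig(rank=2)
        state = _state_for(config, data, rng, zero=True)
        out = mean_tensor(state, data, 0, 1, config=config)
        np.testing.assert_array_equal(out, np.zeros(data.grid.dims))

    def test_slope_only_scales_with_time(self, rng):
        data = tiny_study(rng, n_visits=3)
        data.times = data.visit_of_obs * 2.0  # visit 1 at time 2
        config = ModelConfig(rank=2)
        state = _state_for(config, data, rng, zero=True)
        gamma = random_cp(rng, data.grid.dims, 2)
        state.families["Gamma"] = FamilyState(
            gamma, np.ones((3, 2)), np.ones((3, 2)), np.ones((3, 2)), 1.0
        )
        out = mean_tensor(state, data, 0, 1, config=config)
        np.testing.assert_allclose(out, 2.0 * reconstruct(gamma), atol=1e-12)

    def test_matches_voxelwise_evaluation(self, rng):
        """The tensor mean equals the per-voxel regression equation."""
        data = tiny_study(rng, dims=(3, 3, 3), M=1, S=1, Q=2)
        config = ModelConfig(rank=2)
        state = _state_for(config, data, rng)
        i, t = 1, 1
        a = data.obs_index(i, t)
        out = mean_tensor(state, data, i, t, config=config)
        dense = {k: reconstruct(v.cp) for k, v in state.families.items()}
        T = data.times[a]
        for v in np.ndindex(*data.grid.dims):
            expected = (
                dense["M"][v]
                + dense[f"B[{i}]"][v]
                + dense["Gamma"][v] * T
                + dense[f"Theta[{i}]"][v] * T
                + dense[f"Bt[{t},0]"][v] * data.C[i, 0]
                + dense["D[0]"][v] * data.X[i, 0]
                + dense["C[0]"][v] * data.Z[a, 0]
                + dense["C[1]"][v] * data.Z[a, 1]
            )
            assert out[v] == pytest.approx(expected, rel=1e-10)

    def test_linearity_in_covariates_and_time(self, rng):
        data = tiny_study(rng, M=0, S=1, Q=0)
        config = ModelConfig(rank=1, include_subject_slope=False)
        state = _state_for(config, data, rng, rank=1)
        out1 = mean_tensor(state, data, 0, 1, config=config)
        data.X[0, 0] *= 3.0
        data.times = data.times * 2.0
        out2 = mean_tensor(state, data, 0, 1, config=config)
        dense_d = reconstruct(state.families["D[0]"].cp)
        dense_g = reconstruct(state.families["Gamma"].cp)
        x_old = data.X[0, 0] / 3.0
        np.testing.assert_allclose(
            out2 - out1, 2.0 * x_old * dense_d + 1.0 * dense_g, atol=1e-10
        )

    def test_cross_sectional_mean_ignores_visit(self, rng):
        data = tiny_study(rng, n_visits=3, M=1, S=1, Q=1)
        data.Z[:] = 0.7  # identical time-varying covariates across visits
        config = ModelConfig(rank=1, mode="cross_sectional")
        state = _state_for(config, data, rng, rank=1)
        means = [mean_tensor(state, data, 0, t, config=config) for t in range(3)]
        np.testing.assert_allclose(means[0], means[1], atol=1e-12)
        np.testing.assert_allclose(means[0], means[2], atol=1e-12)


class TestPriorCoefficientCovariance:
    def test_zero_displacement_is_prior_variance(self, rng):
        w = rng.random((3, 2)) + 0.5
        alpha = rng.random(2)
        val = prior_coefficient_covariance(w, alpha, 0)
        assert val == pytest.approx(float(np.sum(np.prod(w, axis=0))))

    def test_rank1_unit_parameters(self):
        val = prior_coefficient_covariance(np.ones((3, 1)), np.ones(1), 1)
        assert val == pytest.approx(np.exp(-1.0))

    def test_monte_carlo_matches_closed_form(self, rng):
        """Empirical covariance of CP coefficients under sampled margins.

        Margins are drawn from N(0, w * Lambda(alpha)) per mode and
        channel; the covariance between coefficients at voxels displaced
        along mode 1 must match sum_r w1 w2 w3 exp(-alpha_1 d^2).
        """
        dims, R, n = (4, 3, 3), 2, 50_000
        w = np.array([[0.8, 1.3], [0.6, 1.0], [1.2, 0.4]])
        alpha = np.array([[0.7, 0.2], [1.0, 1.0], [0.5, 2.0]])
        vox_a, vox_b = (0, 1, 2), (2, 1, 2)  # displaced along mode 1 by 2
        coef_a = np.zeros(n)
        coef_b = np.zeros(n)
        margins = {}
        for d, p in enumerate(dims):
            for r in range(R):
                lam = build_margin_covariance(w[d, r], alpha[d, r], p)
                chol = np.linalg.cholesky(lam + 1e-12 * np.eye(p))
                margins[d, r] = rng.standard_normal((n, p)) @ chol.T
        for r in range(R):
            term_a = np.ones(n)
            term_b = np.ones(n)
            for d in range(3):
                term_a *= margins[d, r][:, vox_a[d]]
                term_b *= margins[d, r][:, vox_b[d]]
            coef_a += term_a
            coef_b += term_b
        centered = (coef_a - coef_a.mean()) * (coef_b - coef_b.mean())
        emp_cov = centered.mean()
        se = centered.std(ddof=1) / np.sqrt(n)
        expected = prior_coefficient_covariance(w, alpha[0], 2)
        assert abs(emp_cov - expected) < 3.0 * se

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            prior_coefficient_covariance(np.ones((2, 2)), np.ones(2), 1)


class TestStudyDataValidation:
    def test_nonzero_baseline_time_rejected(self, rng):
        data = tiny_study(rng)
        with pytest.raises(ValueError, match="baseline"):
            StudyData(
                grid=data.grid,
                subject_of_obs=data.subject_of_obs,
                visit_of_obs=data.visit_of_obs,
                times=data.times + 1.0,
                Y=data.Y,
                obs_mask=data.obs_mask,
                C=data.C,
                X=data.X,
                Z=data.Z,
            )

    def test_cross_sectional_config_disables_longitudinal_terms(self, rng):
        data = tiny_study(rng, M=1)
        keys = [f.key for f in build_families(ModelConfig(mode="cross_sectional"), data)]
        assert "Gamma" not in keys
        assert not any(k.startswith(("B[", "Theta[")) for k in keys)
        assert "Bt[0]" in keys  # collapsed, time-invariant effect
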