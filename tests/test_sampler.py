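"""Gibbs/MH block updates: conjugate distributions, recovery, determinism."""

import numpy as np
import pytest

from btrr.model import ModelConfig, PriorHyperparams, StudyData
from btrr.sampler import GibbsSampler, McmcSettings, run_mcmc, stationarity_diagnostics
from btrr.simulate import SchemeSpec, generate
from btrr.tensor_core import CPTensor, VoxelGrid, reconstruct

from conftest import tiny_study


def _scalar_study(y, observed=True):
    """A 1x1x1 grid with a single subject and visit."""
    return StudyData(
        grid=VoxelGrid((1, 1, 1)),
        subject_of_obs=np.array([0]),
        visit_of_obs=np.array([0]),
        times=np.array([0.0]),
        Y=np.full((1, 1, 1, 1), y),
        obs_mask=np.full((1, 1, 1, 1), observed),
        C=np.zeros((1, 0)),
        X=np.zeros((1, 0)),
        Z=np.zeros((1, 0)),
    )


_INTERCEPT_ONLY = dict(
    include_subject_intercept=False,
    include_population_slope=False,
    include_subject_slope=False,
)


class TestMarginConditional:
    def test_scalar_normal_normal_conjugacy(self):
        """1x1x1 grid: posterior moments match the hand-worked formula."""
        y, sigma2, tau, w = 2.0, 0.5, 1.3, 0.7
        data = _scalar_study(y)
        sampler = GibbsSampler(data, ModelConfig(rank=1, **_INTERCEPT_ONLY))
        rng = np.random.default_rng(0)
        state = sampler.init_state(rng)
        fs = state.families["M"]
        for d in range(3):
            fs.cp.margins[d][:] = 1.0
        fs.tau, fs.w[:] = tau, w
        state.sigma2 = sigma2
        sampler.set_state(state)
        fam = sampler.families[0]
        hr = sampler._hr["M"]
        H2O = sampler._H2O["M"]
        resid_plus = sampler._resid + sampler._HO["M"] * reconstruct(fs.cp)
        draws = np.array([
            sampler.update_margin(fam, 0, 0, rng, resid_plus, H2O, hr)[0]
            for _ in range(20000)
        ])
        prior_var = tau * w
        post_var = 1.0 / (1.0 / prior_var + 1.0 / sigma2)
        post_mean = post_var * y / sigma2
        assert draws.mean() == pytest.approx(post_mean, abs=5 * np.sqrt(post_var / 20000))
        assert draws.var() == pytest.approx(post_var, rel=0.05)

    def test_no_data_conditional_equals_prior(self):
        """With every voxel unobserved the full conditional is the prior."""
        data = _scalar_study(0.0, observed=False)
        data = StudyData(
            grid=VoxelGrid((3, 1, 1)),
            subject_of_obs=np.array([0]),
            visit_of_obs=np.array([0]),
            times=np.array([0.0]),
            Y=np.zeros((1, 3, 1, 1)),
            obs_mask=np.zeros((1, 3, 1, 1), dtype=bool),
            C=np.zeros((1, 0)), X=np.zeros((1, 0)), Z=np.zeros((1, 0)),
        )
        sampler = GibbsSampler(data, ModelConfig(rank=1, **_INTERCEPT_ONLY))
        rng = np.random.default_rng(1)
        state = sampler.init_state(rng)
        fs = state.families["M"]
        fs.tau, fs.w[:], fs.alpha[:] = 2.0, 0.5, 0.8
        sampler.set_state(state)
        fam = sampler.families[0]
        draws = np.array([
            sampler.update_margin(
                fam, 0, 0, rng, sampler._resid, sampler._H2O["M"], sampler._hr["M"]
            )
            for _ in range(10000)
        ])
        k = np.arange(3)
        expected_cov = 2.0 * 0.5 * np.exp(-0.8 * (k[:, None] - k[None, :]) ** 2)
        np.testing.assert_allclose(draws.mean(axis=0), 0.0, atol=0.05)
        np.testing.assert_allclose(np.cov(draws.T), expected_cov, atol=0.06)


class TestScaleConditionals:
    def test_sigma2_with_no_data_samples_prior(self):
        data = _scalar_study(0.0, observed=False)
        priors = PriorHyperparams(a_eps=3.0, b_eps=3.0)
        sampler = GibbsSampler(data, ModelConfig(rank=1, **_INTERCEPT_ONLY), priors)
        rng = np.random.default_rng(2)
        sampler.init_state(rng)
        draws = np.empty(20000)
        for i in range(len(draws)):
            sampler.update_sigma2(rng)
            draws[i] = sampler.state.sigma2
        assert draws.mean() == pytest.approx(3.0 / (3.0 - 1.0), rel=0.05)  # IG mean

    def test_lambda_exponential_gamma_conjugacy(self, rng):
        """lambda | w=2 with unit hyperparameters is Gamma(2, 2), mean 1."""
        data = tiny_study(rng, dims=(2, 2, 2), M=0, S=0, Q=0)
        sampler = GibbsSampler(data, ModelConfig(rank=1, **_INTERCEPT_ONLY))
        sampler.init_state(rng)
        draws = np.empty(3000)
        for i in range(len(draws)):
            sampler.state.families["M"].w[:] = 2.0
            sampler.update_scales(rng)
            draws[i] = sampler.state.families["M"].lam[0, 0]
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert draws.mean() == pytest.approx(1.0, abs=5 * se)


class TestLengthscaleUpdate:
    def test_vanishing_proposal_variance_freezes_chain(self, rng):
        data = tiny_study(rng, dims=(3, 3, 3), M=0, S=0, Q=0)
        priors = PriorHyperparams(sigma_alpha2=1e-30)
        sampler = GibbsSampler(data, ModelConfig(rank=1, **_INTERCEPT_ONLY), priors)
        sampler.init_state(rng)
        before = {k: f.alpha.copy() for k, f in sampler.state.families.items()}
        for _ in range(20):
            sampler.sweep(rng)
        for k, f in sampler.state.families.items():
            np.testing.assert_allclose(f.alpha, before[k], rtol=1e-9)

    def test_flat_likelihood_recovers_gamma_prior(self):
        """Degenerate 1x1x1 extents make the margin term alpha-free, so the
        MH chain must sample the Gamma(a, b) lengthscale prior."""
        data = _scalar_study(0.0, observed=False)
        priors = PriorHyperparams(a_alpha=2.0, b_alpha=1.0, sigma_alpha2=1.0)
        sampler = GibbsSampler(data, ModelConfig(rank=1, **_INTERCEPT_ONLY), priors)
        rng = np.random.default_rng(3)
        state = sampler.init_state(rng)
        state.families["M"].cp.margins[0][:] = 0.0
        sampler.set_state(state)
        fam = sampler.families[0]
        trace = np.empty(30000)
        for i in range(len(trace)):
            sampler.update_lengthscale(fam, 0, rng)
            trace[i] = sampler.state.families["M"].alpha[0, 0]
        assert trace.mean() == pytest.approx(2.0, rel=0.1)  # a/b
        assert trace.var() == pytest.approx(2.0, rel=0.25)  # a/b^2

    def test_acceptance_rates_are_tracked(self, rng):
        data = tiny_study(rng, dims=(3, 3, 3), M=0, S=0, Q=0)
        sampler = GibbsSampler(data, ModelConfig(rank=1, **_INTERCEPT_ONLY))
        sampler.init_state(rng)
        for _ in range(30):
            sampler.sweep(rng)
        rates = sampler.alpha_accepted["M"] / sampler.alpha_proposed["M"]
        assert np.all((0.0 <= rates) & (rates <= 1.0))
        assert rates.mean() > 0.05  # the chain moves


class TestRunMcmc:
    def test_fixed_seed_reproduces_chain_bitwise(self, rng):
        data = tiny_study(rng, dims=(3, 3, 3), n_subjects=2, n_visits=2)
        cfg = ModelConfig(rank=1)
        settings = McmcSettings(n_iter=30, burn_in=10, seed=99)
        d1 = run_mcmc(data, cfg, settings=settings, store_families="all")
        d2 = run_mcmc(data, cfg, settings=settings, store_families="all")
        np.testing.assert_array_equal(d1.sigma2, d2.sigma2)
        for k in d1.coef_draws:
            np.testing.assert_array_equal(d1.coef_draws[k], d2.coef_draws[k])

    def test_noiseless_slope_recovery(self, rng):
        """Rank-1 slope-only data is recovered to well under 10% of signal RMS."""
        dims, n, T = (8, 8, 8), 14, 3
        A = n * T
        gamma = CPTensor(dims, [np.abs(rng.standard_normal((p, 1))) + 0.2 for p in dims])
        dense = reconstruct(gamma)
        subj = np.repeat(np.arange(n), T)
        visit = np.tile(np.arange(T), n)
        times = visit.astype(float)
        data = StudyData(
            grid=VoxelGrid(dims), subject_of_obs=subj, visit_of_obs=visit,
            times=times, Y=times[:, None, None, None] * dense[None],
            obs_mask=np.ones((A, *dims), dtype=bool),
            C=np.zeros((n, 0)), X=np.zeros((n, 0)), Z=np.zeros((A, 0)),
        )
        cfg = ModelConfig(rank=1, include_intercept=False,
                          include_subject_intercept=False, include_subject_slope=False)
        draws = run_mcmc(data, cfg, settings=McmcSettings(n_iter=400, burn_in=200, seed=4))
        est = draws.coef_mean["Gamma"]
        c_rmse = np.sqrt(np.mean((est - dense) ** 2))
        signal_rms = np.sqrt(np.mean(dense**2))
        assert c_rmse < 0.1 * signal_rms

    def test_visit_permutation_invariance_cross_sectional(self, rng):
        """With subject terms off and equal z, permuting a subject's visits
        leaves a sweep's output unchanged (up to float summation order)."""
        dims = (3, 3, 3)
        n, T = 2, 2
        A = n * T
        Y = rng.standard_normal((A, *dims))
        base = dict(
            grid=VoxelGrid(dims),
            obs_mask=np.ones((A, *dims), dtype=bool),
            C=np.zeros((n, 0)), X=rng.standard_normal((n, 1)),
        )
        subj = np.array([0, 0, 1, 1])
        data1 = StudyData(subject_of_obs=subj, visit_of_obs=np.array([0, 1, 0, 1]),
                          times=np.array([0.0, 1.0, 0.0, 1.0]), Y=Y,
                          Z=np.full((A, 1), 0.4), **base)
        perm = np.array([1, 0, 2, 3])  # swap subject 0's visits
        data2 = StudyData(subject_of_obs=subj, visit_of_obs=np.array([0, 1, 0, 1]),
                          times=np.array([0.0, 1.0, 0.0, 1.0]), Y=Y[perm],
                          Z=np.full((A, 1), 0.4), **base)
        cfg = ModelConfig(rank=1, mode="cross_sectional")
        out = []
        for data in (data1, data2):
            sampler = GibbsSampler(data, cfg)
            st_rng = np.random.default_rng(11)
            sampler.init_state(st_rng)
            sampler.sweep(st_rng)
            out.append(sampler.state)
        assert out[0].sigma2 == pytest.approx(out[1].sigma2, rel=1e-8)
        for k in out[0].families:
            for d in range(3):
                np.testing.assert_allclose(
                    out[0].families[k].cp.margins[d],
                    out[1].families[k].cp.margins[d], atol=1e-8,
                )

    def test_leakage_guard_on_targets(self, rng):
        data = tiny_study(rng, dims=(3, 3, 3))
        with pytest.raises(ValueError, match="overlap"):
            run_mcmc(
                data, ModelConfig(rank=1),
                settings=McmcSettings(n_iter=4, burn_in=2, seed=0),
                predict_targets=np.array([[0, 0, 0, 0]]),
            )


@pytest.fixture(scope="module")
def scheme1_fit():
    from btrr.experiments import run_replicate

    spec = SchemeSpec(scheme="1", dims=(8, 8, 8), seed=7)
    return spec, run_replicate(spec, n_iter=600, burn_in=300)


class TestFitQualityOnSyntheticData:
    def test_noise_variance_recovered_within_10_percent(self, scheme1_fit):
        _, report = scheme1_fit
        assert report.extras["sigma2_post_mean"] == pytest.approx(
            report.extras["sigma2_true"], rel=0.10
        )

    def test_selection_f1_exceeds_three_quarters(self, scheme1_fit):
        _, report = scheme1_fit
        assert report.f1 > 0.75

    def test_prediction_beats_voxel_mean_baseline(self, scheme1_fit):
        spec, report = scheme1_fit
        rep = generate(spec)
        a, j1, j2, j3 = rep.holdout_targets.T
        # baseline: per-voxel mean of the training observations
        Ymask = np.where(rep.data.obs_mask, rep.data.Y, np.nan)
        voxel_mean = np.nanmean(Ymask, axis=0)
        baseline = voxel_mean[j1, j2, j3]
        base_rmse = np.sqrt(np.mean((baseline - rep.holdout_observed) ** 2))
        assert report.p_rmse < base_rmse


class TestStationarityDiagnostics:
    def test_white_noise_passes(self, rng):
        traces = rng.standard_normal((200, 40))
        _, frac = stationarity_diagnostics(traces)
        assert frac >= 0.85

    def test_linear_trend_fails(self):
        trend = np.linspace(0.0, 5.0, 200)[:, None] + 0.0
        pvals, frac = stationarity_diagnostics(np.hstack([trend, trend * -2]))
        assert frac == 0.0 and np.all(pvals > 0.05)

    def test_constant_trace_trivially_stationary(self):
        pvals, frac = stationarity_diagnostics(np.ones((100, 3)))
        assert frac == 1.0 and np.all(pvals == 0.0)

    def test_requires_minimum_draws(self, rng):
        with pytest.raises(ValueError):
            stationarity_diagnostics(rng.standard_normal((10, 2)))
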