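"""MCMC posterior computation for the longitudinal tensor regression model.

A systematic-scan Gibbs sampler with closed-form full conditionals for
every block except the lengthscales:

* margin vectors ``u_{d,r}``: Gaussian, exploiting that conditional on
  the other two modes each margin enters the mean linearly;
* margin variances ``w_{d,r}``: generalized inverse Gaussian (from the
  exponential prior times the Gaussian margin likelihood);
* rates ``lambda_{d,r}``: Gamma (exponential-Gamma conjugacy);
* global scales ``tau``: the Gamma prior is interpreted as acting on the
  precision ``1/tau``, giving a conjugate Gamma update;
* residual variance ``sigma2``: inverse Gamma;
* lengthscales ``alpha_{d,r}``: Metropolis-Hastings with a log-normal
  random walk (the Hastings ratio includes the log-scale Jacobian).

The likelihood sums only over voxels observed for each (subject, visit);
held-out or lesioned voxels contribute nothing and are predicted post
hoc.  All randomness flows through one ``numpy.random.Generator`` so a
fixed seed yields a bitwise-reproducible chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_solve, solve_triangular

from ._gig import gig_rvs
from .model import (
    FamilySpec,
    FamilyState,
    ModelConfig,
    ModelState,
    PriorHyperparams,
    StudyData,
    build_families,
)
from .tensor_core import CPTensor, reconstruct

logger = logging.getLogger(__name__)

_JITTER = 1e-8

__all__ = [
    "McmcSettings",
    "PosteriorDraws",
    "GibbsSampler",
    "run_mcmc",
    "stationarity_diagnostics",
]


@dataclass
class McmcSettings:
    """Chain length, seed and block-update switches."""

    n_iter: int = 5000
    burn_in: int = 2500
    thinning: int = 1
    seed: int = 0
    update_margins: bool = True
    update_scales: bool = True
    update_lengthscales: bool = True
    update_sigma2: bool = True
    residual_refresh_every: int = 200

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("require 0 <= burn_in < n_iter")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    @property
    def n_stored(self) -> int:
        return (self.n_iter - self.burn_in) // self.thinning


@dataclass
class PosteriorDraws:
    """Post-burn-in posterior draws and run metadata.

    Dense coefficient draws are stored only for the requested families
    (storing everything at full resolution is rarely needed); running
    posterior means are kept for *all* families, which is what deviance
    and DIC computations require.
    """

    family_keys: list[str]
    coef_draws: dict[str, np.ndarray]  # key -> (J, p1, p2, p3)
    coef_mean: dict[str, np.ndarray]  # key -> (p1, p2, p3)
    sigma2: np.ndarray  # (J,)
    deviance: np.ndarray  # (J,)
    tau_trace: np.ndarray  # (J, n_families)
    alpha_accept: dict[str, np.ndarray]  # key -> (3, R) acceptance rates
    n_obs_voxels: int
    predict_targets: np.ndarray | None = None  # (T, 4) rows (a, j1, j2, j3)
    predictive: np.ndarray | None = None  # (J, T) mean + noise draw
    predictive_mean: np.ndarray | None = None  # (J, T) noise-free fitted mean
    fitted_trace: np.ndarray | None = None  # (J, n_voxels)

    @property
    def n_draws(self) -> int:
        return len(self.sigma2)

    def sigma2_mean(self) -> float:
        return float(self.sigma2.mean())


def _lambda_matrix(alpha: np.ndarray, p: int) -> np.ndarray:
    """Batched squared-exponential correlation with a small diagonal jitter."""
    k = np.arange(p, dtype=float)
    d2 = (k[:, None] - k[None, :]) ** 2
    lam = np.exp(-np.asarray(alpha, dtype=float)[..., None, None] * d2)
    lam[..., np.arange(p), np.arange(p)] += _JITTER
    return lam


class GibbsSampler:
    """Stateful Gibbs/MH sampler bound to one dataset and model config."""

    def __init__(
        self,
        data: StudyData,
        config: ModelConfig,
        priors: PriorHyperparams | None = None,
    ) -> None:
        self.data = data
        self.config = config
        self.priors = priors or PriorHyperparams()
        self.families: list[FamilySpec] = build_families(config, data)
        if not self.families:
            raise ValueError("model configuration enables no coefficient families")
        self.dims = data.grid.dims
        self.A = data.n_obs
        self._Of = data.obs_mask.astype(float)
        self.n_obs_voxels = int(data.obs_mask.sum())
        # an all-masked study is allowed: every conditional reduces to its prior
        # per-family precomputed loadings / masked weights
        self._rows: dict[str, np.ndarray] = {}
        self._hr: dict[str, np.ndarray] = {}
        self._HO: dict[str, np.ndarray] = {}
        self._H2O: dict[str, np.ndarray] = {}
        self._full: dict[str, bool] = {}
        for fam in self.families:
            h = fam.loading
            rows = np.flatnonzero(h != 0.0)
            self._rows[fam.key] = rows
            hr = h[rows]
            self._hr[fam.key] = hr
            Orow = self._Of[rows]
            self._HO[fam.key] = hr[:, None, None, None] * Orow
            self._H2O[fam.key] = (hr**2)[:, None, None, None] * Orow
            self._full[fam.key] = len(rows) == self.A
        self.state: ModelState | None = None
        self._resid: np.ndarray | None = None
        # per-family caches keyed by family, then mode: (R, p_d, p_d) etc.
        self._chol: dict[str, list[np.ndarray]] = {}
        self._laminv: dict[str, list[np.ndarray]] = {}
        self._logdet: dict[str, list[np.ndarray]] = {}
        self.alpha_accepted: dict[str, np.ndarray] = {}
        self.alpha_proposed: dict[str, np.ndarray] = {}

    # ------------------------------------------------------------------
    # state initialisation
    # ------------------------------------------------------------------
    def _fresh_family(self, rank: int) -> FamilyState:
        pr = self.priors
        cp = CPTensor.zeros(self.dims, rank)
        w0 = 2.0 * pr.b_lam / pr.a_lam  # prior mean of Exp(lambda/2) at E[lambda]
        return FamilyState(
            cp=cp,
            w=np.full((3, rank), w0),
            lam=np.full((3, rank), pr.a_lam / pr.b_lam),
            alpha=np.full((3, rank), pr.a_alpha / pr.b_alpha),
            tau=1.0,
        )

    def init_state(self, rng: np.random.Generator, margin_sd: float = 0.1) -> ModelState:
        """Default start: small random margins, scales at prior-mean values."""
        R = self.config.rank
        fams = {}
        for fam in self.families:
            fs = self._fresh_family(R)
            for d, p in enumerate(self.dims):
                fs.cp.margins[d][:] = margin_sd * rng.standard_normal((p, R))
            fams[fam.key] = fs
        state = ModelState(fams, sigma2=1.0)
        self.set_state(state)
        return state

    def draw_prior_state(self, rng: np.random.Generator) -> ModelState:
        """Exact draw from the prior hierarchy (used by the Geweke validation)."""
        pr = self.priors
        R = self.config.rank
        fams = {}
        for fam in self.families:
            fs = self._fresh_family(R)
            fs.tau = 1.0 / rng.gamma(pr.a_tau, 1.0 / pr.b_tau)
            fs.lam = rng.gamma(pr.a_lam, 1.0 / pr.b_lam, size=(3, R))
            fs.w = rng.exponential(2.0 / fs.lam)
            fs.alpha = rng.gamma(pr.a_alpha, 1.0 / pr.b_alpha, size=(3, R))
            for d, p in enumerate(self.dims):
                lam_d = _lambda_matrix(fs.alpha[d], p)
                chol = np.linalg.cholesky(lam_d)
                z = rng.standard_normal((R, p))
                for r in range(R):
                    sd = np.sqrt(fs.tau * fs.w[d, r])
                    fs.cp.margins[d][:, r] = sd * (chol[r] @ z[r])
            fams[fam.key] = fs
        sigma2 = (pr.b_eps) / rng.gamma(pr.a_eps)
        state = ModelState(fams, sigma2=float(sigma2))
        self.set_state(state)
        return state

    def set_state(self, state: ModelState) -> None:
        self.state = state
        for fam in self.families:
            fs = state.families[fam.key]
            self._chol[fam.key] = []
            self._laminv[fam.key] = []
            self._logdet[fam.key] = []
            for d, p in enumerate(self.dims):
                lam_d = _lambda_matrix(fs.alpha[d], p)
                chol = np.linalg.cholesky(lam_d)
                self._chol[fam.key].append(chol)
                eye = np.eye(p)
                inv = np.stack([cho_solve((chol[r], True), eye)
                                for r in range(fs.cp.rank)])
                self._laminv[fam.key].append(inv)
                self._logdet[fam.key].append(
                    2.0 * np.log(np.diagonal(chol, axis1=1, axis2=2)).sum(axis=1)
                )
            self.alpha_accepted[fam.key] = np.zeros((3, fs.cp.rank))
            self.alpha_proposed[fam.key] = np.zeros((3, fs.cp.rank))
        self._refresh_residuals()

    # ------------------------------------------------------------------
    # residual bookkeeping
    # ------------------------------------------------------------------
    def mean_stack(self, state: ModelState | None = None) -> np.ndarray:
        """Fitted mean for every observation, shape (A, p1, p2, p3)."""
        state = state or self.state
        out = np.zeros((self.A, *self.dims))
        for fam in self.families:
            dense = reconstruct(state.families[fam.key].cp)
            h = fam.loading
            rows = self._rows[fam.key]
            out[rows] += self._hr[fam.key][:, None, None, None] * dense[None]
        return out

    def _refresh_residuals(self) -> None:
        self._resid = self._Of * (self.data.Y - self.mean_stack())

    def set_outcomes(self, Y: np.ndarray) -> None:
        """Replace outcome images (used by validation simulators)."""
        if Y.shape != self.data.Y.shape:
            raise ValueError("outcome shape mismatch")
        self.data.Y = np.asarray(Y, dtype=float)
        self._refresh_residuals()

    def draw_outcomes(self, rng: np.random.Generator) -> np.ndarray:
        """Sample outcomes from the likelihood at the current state."""
        mean = self.mean_stack()
        noise = rng.standard_normal(mean.shape) * np.sqrt(self.state.sigma2)
        return self.data.obs_mask * (mean + noise)

    def rss(self) -> float:
        return float(np.vdot(self._resid, self._resid))

    def log_likelihood(self) -> float:
        s2 = self.state.sigma2
        return -0.5 * (self.n_obs_voxels * np.log(2 * np.pi * s2) + self.rss() / s2)

    def deviance(self) -> float:
        return -2.0 * self.log_likelihood()

    # ------------------------------------------------------------------
    # block updates
    # ------------------------------------------------------------------
    _EINSUM_P = ["aijk,jk->i", "aijk,ik->j", "aijk,ij->k"]
    _EINSUM_B = ["a,aijk,jk->i", "a,aijk,ik->j", "a,aijk,ij->k"]

    def _other_outer(self, margins: list[np.ndarray], d: int, r: int) -> np.ndarray:
        o1, o2 = [a for a in range(3) if a != d]
        return np.outer(margins[o1][:, r], margins[o2][:, r])

    def update_margin(
        self,
        fam: FamilySpec,
        d: int,
        r: int,
        rng: np.random.Generator,
        resid_plus: np.ndarray,
        H2O: np.ndarray,
        hr: np.ndarray,
    ) -> np.ndarray:
        """Draw one margin vector from its Gaussian full conditional.

        ``resid_plus`` must hold the masked residuals with this channel's
        contribution *added back* for the family's rows.
        """
        fs = self.state.families[fam.key]
        s2 = self.state.sigma2
        G = self._other_outer(fs.cp.margins, d, r)
        prec_diag = np.einsum(self._EINSUM_P[d], H2O, G * G) / s2
        b = np.einsum(self._EINSUM_B[d], hr, resid_plus, G) / s2
        prior_prec = self._laminv[fam.key][d][r] / (fs.tau * fs.w[d, r])
        post_prec = prior_prec + np.diag(prec_diag)
        try:
            L = np.linalg.cholesky(post_prec)
        except np.linalg.LinAlgError:
            logger.warning(
                "jitter-regularized margin solve for %s mode %d channel %d",
                fam.key, d, r,
            )
            post_prec = post_prec + 1e-8 * np.max(np.diag(post_prec)) * np.eye(
                post_prec.shape[0]
            )
            L = np.linalg.cholesky(post_prec)
        mean = cho_solve((L, True), b)
        z = rng.standard_normal(len(b))
        draw = mean + solve_triangular(L, z, lower=True, trans="T")
        if not np.all(np.isfinite(draw)):
            raise FloatingPointError(
                f"non-finite margin draw for family {fam.key}, mode {d}, channel {r}"
            )
        return draw

    def _update_family_margins(self, fam: FamilySpec, rng: np.random.Generator) -> None:
        fs = self.state.families[fam.key]
        key = fam.key
        rows = self._rows[key]
        hr = self._hr[key]
        HO = self._HO[key]
        H2O = self._H2O[key]
        full = self._full[key]
        margins = fs.cp.margins
        tmp = self._resid if full else self._resid[rows]
        for r in range(fs.cp.rank):
            contrib = np.einsum(
                "i,j,k->ijk", margins[0][:, r], margins[1][:, r], margins[2][:, r]
            )
            tmp += HO * contrib
            for d in range(3):
                margins[d][:, r] = self.update_margin(fam, d, r, rng, tmp, H2O, hr)
            contrib = np.einsum(
                "i,j,k->ijk", margins[0][:, r], margins[1][:, r], margins[2][:, r]
            )
            tmp -= HO * contrib
        if not full:
            self._resid[rows] = tmp

    def _quad_forms(self, fam: FamilySpec) -> np.ndarray:
        """q[d, r] = u_{d,r}' Lambda^{-1} u_{d,r} for one family."""
        fs = self.state.families[fam.key]
        q = np.empty((3, fs.cp.rank))
        for d in range(3):
            U = fs.cp.margins[d]  # (p, R)
            inv = self._laminv[fam.key][d]  # (R, p, p)
            q[d] = np.einsum("rpq,pr,qr->r", inv, U, U)
        return q

    def update_scales(self, rng: np.random.Generator) -> None:
        """Gibbs draws of lambda, w (GIG) and tau (precision-conjugate)."""
        pr = self.priors
        quads = {fam.key: self._quad_forms(fam) for fam in self.families}
        # lambda | w  ~ Gamma(a_l + 1, b_l + w/2)
        for fam in self.families:
            fs = self.state.families[fam.key]
            fs.lam = rng.gamma(pr.a_lam + 1.0, 1.0 / (pr.b_lam + fs.w / 2.0))
        # w | margin ~ GIG(1 - p_d/2, lambda, q / tau), batched across blocks
        orders, rates_a, rates_b, slots = [], [], [], []
        for fam in self.families:
            fs = self.state.families[fam.key]
            for d, p in enumerate(self.dims):
                for r in range(fs.cp.rank):
                    orders.append(1.0 - p / 2.0)
                    rates_a.append(fs.lam[d, r])
                    rates_b.append(max(quads[fam.key][d, r] / fs.tau, 1e-12))
                    slots.append((fam.key, d, r))
        draws = gig_rvs(np.array(orders), np.array(rates_a), np.array(rates_b), rng)
        if not np.all(np.isfinite(draws)):
            bad = slots[int(np.flatnonzero(~np.isfinite(draws))[0])]
            raise FloatingPointError(f"non-finite margin-variance draw at {bad}")
        for val, (key, d, r) in zip(draws, slots):
            self.state.families[key].w[d, r] = val
        # 1/tau ~ Gamma(a_t + R * sum_d p_d / 2, b_t + sum q / (2 w))
        half_dim = 0.5 * sum(self.dims)
        for fam in self.families:
            fs = self.state.families[fam.key]
            shape = pr.a_tau + fs.cp.rank * half_dim
            rate = pr.b_tau + float(np.sum(quads[fam.key] / (2.0 * fs.w)))
            fs.tau = 1.0 / rng.gamma(shape, 1.0 / rate)
        self._quads_cache = quads

    def update_lengthscale(self, fam: FamilySpec, d: int, rng: np.random.Generator,
                           quads: np.ndarray | None = None) -> None:
        """Log-normal random-walk MH for alpha_{d, 1..R} of one family."""
        pr = self.priors
        fs = self.state.families[fam.key]
        R = fs.cp.rank
        p = self.dims[d]
        alpha = fs.alpha[d]
        U = fs.cp.margins[d]
        q_cur = (
            quads[d]
            if quads is not None
            else np.einsum("rpq,pr,qr->r", self._laminv[fam.key][d], U, U)
        )
        logdet_cur = self._logdet[fam.key][d]
        sd = np.sqrt(pr.sigma_alpha2)
        prop = alpha * np.exp(sd * rng.standard_normal(R))
        lam_prop = _lambda_matrix(prop, p)
        chol_prop = np.linalg.cholesky(lam_prop)
        logdet_prop = 2.0 * np.log(np.diagonal(chol_prop, axis1=1, axis2=2)).sum(axis=1)
        y = np.linalg.solve(lam_prop, U.T[..., None])[..., 0]  # (R, p)
        q_prop = np.einsum("rp,pr->r", y, U)
        tw = fs.tau * fs.w[d]
        delta = (
            -0.5 * (logdet_prop - logdet_cur)
            - 0.5 * (q_prop - q_cur) / tw
            + pr.a_alpha * (np.log(prop) - np.log(alpha))
            - pr.b_alpha * (prop - alpha)
        )
        accept = np.log(rng.random(R)) < delta
        self.alpha_proposed[fam.key][d] += 1
        self.alpha_accepted[fam.key][d] += accept
        if accept.any():
            fs.alpha[d] = np.where(accept, prop, alpha)
            eye = np.eye(p)
            for r in np.flatnonzero(accept):
                self._chol[fam.key][d][r] = chol_prop[r]
                self._laminv[fam.key][d][r] = cho_solve((chol_prop[r], True), eye)
                self._logdet[fam.key][d][r] = logdet_prop[r]

    def update_sigma2(self, rng: np.random.Generator) -> None:
        pr = self.priors
        shape = pr.a_eps + 0.5 * self.n_obs_voxels
        rate = pr.b_eps + 0.5 * self.rss()
        self.state.sigma2 = float(rate / rng.gamma(shape))

    def sweep(
        self,
        rng: np.random.Generator,
        settings: McmcSettings | None = None,
    ) -> None:
        """One systematic scan over all blocks (sigma2 last)."""
        s = settings or McmcSettings()
        if s.update_margins:
            for fam in self.families:
                self._update_family_margins(fam, rng)
        if s.update_scales:
            self.update_scales(rng)
            quads_cache = self._quads_cache
        else:
            quads_cache = None
        if s.update_lengthscales:
            for fam in self.families:
                q = quads_cache.get(fam.key) if quads_cache else None
                for d in range(3):
                    self.update_lengthscale(fam, d, rng, quads=q)
        if s.update_sigma2:
            self.update_sigma2(rng)

    # ------------------------------------------------------------------
    # full run
    # ------------------------------------------------------------------
    def run(
        self,
        settings: McmcSettings,
        store_families: list[str] | str | None = None,
        predict_targets: np.ndarray | None = None,
        store_fitted_trace: bool = False,
        initial_state: ModelState | None = None,
    ) -> PosteriorDraws:
        rng = np.random.default_rng(settings.seed)
        if initial_state is not None:
            self.set_state(initial_state)
        else:
            self.init_state(rng)

        keys = [f.key for f in self.families]
        if store_families is None:
            store_keys = [
                f.key for f in self.families if f.kind in ("Bt", "D", "C", "Gamma")
            ]
        elif store_families == "all":
            store_keys = list(keys)
        else:
            store_keys = [k for k in store_families if k in keys]
        J = settings.n_stored
        coef_draws = {k: np.empty((J, *self.dims)) for k in store_keys}
        coef_sum = {k: np.zeros(self.dims) for k in keys}
        sigma2_arr = np.empty(J)
        dev_arr = np.empty(J)
        tau_arr = np.empty((J, len(keys)))
        if predict_targets is not None:
            predict_targets = np.asarray(predict_targets, dtype=int)
            a, j1, j2, j3 = predict_targets.T
            if self.data.obs_mask[a, j1, j2, j3].any():
                raise ValueError("prediction targets overlap the training voxels")
            pred = np.empty((J, len(predict_targets)))
            pred_mean = np.empty((J, len(predict_targets)))
        else:
            pred = pred_mean = None
        fitted = np.empty((J, int(np.prod(self.dims)))) if store_fitted_trace else None

        jstore = 0
        for it in range(settings.n_iter):
            self.sweep(rng, settings)
            if (it + 1) % settings.residual_refresh_every == 0:
                self._refresh_residuals()
            if it < settings.burn_in:
                continue
            if (it - settings.burn_in) % settings.thinning:
                continue
            dense = {k: reconstruct(self.state.families[k].cp) for k in keys}
            for k in keys:
                coef_sum[k] += dense[k]
            for k in store_keys:
                coef_draws[k][jstore] = dense[k]
            sigma2_arr[jstore] = self.state.sigma2
            dev_arr[jstore] = self.deviance()
            tau_arr[jstore] = [self.state.families[k].tau for k in keys]
            if pred is not None:
                vals = np.zeros(len(predict_targets))
                for fam in self.families:
                    h = fam.loading[a]
                    vals += h * dense[fam.key][j1, j2, j3]
                pred_mean[jstore] = vals
                pred[jstore] = vals + np.sqrt(self.state.sigma2) * rng.standard_normal(
                    len(vals)
                )
            if fitted is not None:
                fitted[jstore] = self.mean_stack().mean(axis=0).ravel()
            jstore += 1

        for k in keys:
            coef_sum[k] /= max(jstore, 1)
        rates = {
            k: self.alpha_accepted[k] / np.maximum(self.alpha_proposed[k], 1)
            for k in keys
        }
        for k in keys:
            logger.info("family %s mean MH acceptance %.3f", k, rates[k].mean())
        return PosteriorDraws(
            family_keys=keys,
            coef_draws=coef_draws,
            coef_mean=coef_sum,
            sigma2=sigma2_arr[:jstore],
            deviance=dev_arr[:jstore],
            tau_trace=tau_arr[:jstore],
            alpha_accept=rates,
            n_obs_voxels=self.n_obs_voxels,
            predict_targets=predict_targets,
            predictive=pred[:jstore] if pred is not None else None,
            predictive_mean=pred_mean[:jstore] if pred_mean is not None else None,
            fitted_trace=fitted[:jstore] if fitted is not None else None,
        )


def run_mcmc(
    data: StudyData,
    config: ModelConfig,
    priors: PriorHyperparams | None = None,
    settings: McmcSettings | None = None,
    **run_kwargs,
) -> PosteriorDraws:
    """Fit the model by MCMC and return post-burn-in draws."""
    sampler = GibbsSampler(data, config, priors)
    return sampler.run(settings or McmcSettings(), **run_kwargs)


def stationarity_diagnostics(
    traces: np.ndarray, level: float = 0.05, maxlag: int | None = None
) -> tuple[np.ndarray, float]:
    """Augmented Dickey-Fuller stationarity check on per-voxel MCMC traces.

    Parameters
    ----------
    traces
        Array (J, L): J post-burn-in draws for each of L voxels.
    level
        Significance level; a voxel "passes" when the ADF p-value is
        below it (evidence of stationarity).

    Returns
    -------
    (pvals, passing_fraction).  Constant traces are reported as trivially
    stationary (p-value 0).  This is a convergence report, not a gate.
    """
    from statsmodels.tsa.stattools import adfuller

    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if traces.shape[0] < 50:
        raise ValueError("need at least 50 post-burn-in draws for the ADF test")
    pvals = np.empty(traces.shape[1])
    for l in range(traces.shape[1]):
        x = traces[:, l]
        if np.ptp(x) < 1e-14:
            pvals[l] = 0.0
            continue
        try:
            pvals[l] = adfuller(x, maxlag=maxlag)[1]
        except Exception:  # numerically degenerate trace
            pvals[l] = 0.0
    return pvals, float(np.mean(pvals < level))
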