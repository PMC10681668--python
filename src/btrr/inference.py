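"""Multiplicity-adjusted feature selection and neuroplasticity maps.

Selection uses simultaneous ("Mdev") credible bands over all elements of
a tensor coefficient: pointwise empirical quantiles are widened by the
maximal deviation of those quantiles from the posterior mean across
elements, producing one joint band whose simultaneous coverage delivers
an in-built multiplicity adjustment.  A voxel is declared significant
when its joint band excludes zero (a closed band containing zero, even
at an endpoint, counts as non-significant).

Neuroplasticity between consecutive visits is the model-implied change
in the expected image, computed per MCMC draw so the same band machinery
applies; group maps are iteration-wise averages of member maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import StudyData
from .sampler import PosteriorDraws

__all__ = [
    "BandResult",
    "PlasticityMap",
    "mdev_bands",
    "plasticity_draws",
    "group_plasticity",
    "posterior_predict",
]


@dataclass
class BandResult:
    """A simultaneous credible band over L elements at level alpha."""

    mean: np.ndarray  # (L,) posterior means
    lower_pointwise: np.ndarray  # (L,) alpha/2 empirical quantiles
    upper_pointwise: np.ndarray  # (L,) 1 - alpha/2 empirical quantiles
    zeta_lower: float  # maximal downward deviation
    zeta_upper: float  # maximal upward deviation
    lower: np.ndarray  # (L,) joint band, mean - zeta_lower
    upper: np.ndarray  # (L,) joint band, mean + zeta_upper
    significant: np.ndarray  # (L,) bool, band strictly excludes 0
    alpha: float

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower


def mdev_bands(samples: np.ndarray, alpha: float = 0.05) -> BandResult:
    """Simultaneous credible band from J x L posterior draws.

    Empirical quantiles use linear interpolation (NumPy's default,
    "type 7"); the choice is documented rather than important at the
    chain lengths used here.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim == 1:
        samples = samples[:, None]
    if samples.ndim != 2:
        raise ValueError("samples must be a J x L array")
    J, L = samples.shape
    if J < 2:
        raise ValueError("need at least 2 posterior draws")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if not np.all(np.isfinite(samples)):
        raise ValueError("non-finite posterior draws")
    mean = samples.mean(axis=0)
    lo_pw = np.quantile(samples, alpha / 2.0, axis=0)
    hi_pw = np.quantile(samples, 1.0 - alpha / 2.0, axis=0)
    zeta_lo = float(np.max(mean - lo_pw))
    zeta_hi = float(np.max(hi_pw - mean))
    lower = mean - zeta_lo
    upper = mean + zeta_hi
    significant = (lower > 0.0) | (upper < 0.0)
    return BandResult(
        mean=mean,
        lower_pointwise=lo_pw,
        upper_pointwise=hi_pw,
        zeta_lower=zeta_lo,
        zeta_upper=zeta_hi,
        lower=lower,
        upper=upper,
        significant=significant,
        alpha=alpha,
    )


@dataclass
class PlasticityMap:
    """Per-voxel draws of expected-outcome change between two visits."""

    draws: np.ndarray  # (J, n_voxels) flattened voxel draws
    dims: tuple[int, int, int]
    visit_pair: tuple[int, int]  # (t, t_prev)
    subjects: tuple[int, ...]  # singleton for individual maps
    alpha: float = 0.05

    def bands(self, alpha: float | None = None) -> BandResult:
        return mdev_bands(self.draws, alpha if alpha is not None else self.alpha)

    def significance_volume(self, alpha: float | None = None) -> np.ndarray:
        """Signed significance map: +1 increase, -1 decrease, 0 otherwise."""
        band = self.bands(alpha)
        out = np.zeros(len(band.mean))
        out[band.significant & (band.mean > 0)] = 1.0
        out[band.significant & (band.mean < 0)] = -1.0
        return out.reshape(self.dims)


def _stored(draws: PosteriorDraws, key: str) -> np.ndarray:
    if key not in draws.coef_draws:
        raise KeyError(
            f"family {key!r} was not stored; rerun with store_families including it"
        )
    return draws.coef_draws[key]


def plasticity_draws(
    draws: PosteriorDraws,
    data: StudyData,
    subject: int,
    visit_pair: tuple[int, int] | None = None,
) -> PlasticityMap:
    """Model-implied change for one subject between visits t and t* = t-1.

    Per draw j the change at voxel v is
    ``(Gamma_j + Theta_ij)(v) (T_ti - T_t*i) + sum_m (B_tmj - B_t*mj)(v) c_im
    + sum_q C_qj(v) (z_tiq - z_t*iq)``;
    intercept terms cancel, so this equals the difference of the fitted
    mean images at the two visits.
    """
    if visit_pair is None:
        visit_pair = (data.n_visits - 1, data.n_visits - 2)
    t, t_prev = visit_pair
    a_t = data.obs_index(subject, t)
    a_p = data.obs_index(subject, t_prev)
    dt = data.times[a_t] - data.times[a_p]
    J = draws.n_draws
    p = int(np.prod(data.grid.dims))
    out = np.zeros((J, p))
    keys = set(draws.family_keys)
    if "Gamma" in keys:
        out += dt * _stored(draws, "Gamma").reshape(J, p)
    if f"Theta[{subject}]" in keys:
        out += dt * _stored(draws, f"Theta[{subject}]").reshape(J, p)
    for m in range(data.M):
        k_t, k_p = f"Bt[{t},{m}]", f"Bt[{t_prev},{m}]"
        if k_t in keys:  # longitudinal mode; cross-sectional Bt[m] cancels
            diff = _stored(draws, k_t) - _stored(draws, k_p)
            out += data.C[subject, m] * diff.reshape(J, p)
    for q in range(data.Q):
        dz = data.Z[a_t, q] - data.Z[a_p, q]
        if dz != 0.0 and f"C[{q}]" in keys:
            out += dz * _stored(draws, f"C[{q}]").reshape(J, p)
    return PlasticityMap(
        draws=out, dims=data.grid.dims, visit_pair=visit_pair, subjects=(subject,)
    )


def group_plasticity(maps: list[PlasticityMap]) -> PlasticityMap:
    """Iteration-wise average of individual maps over a subject group."""
    if not maps:
        raise ValueError("empty group")
    first = maps[0]
    for m in maps[1:]:
        if m.dims != first.dims or m.visit_pair != first.visit_pair:
            raise ValueError("group members must share grid and visit pair")
        if m.draws.shape != first.draws.shape:
            raise ValueError("group members must share the draw count")
    draws = np.mean([m.draws for m in maps], axis=0)
    subjects = tuple(s for m in maps for s in m.subjects)
    return PlasticityMap(
        draws=draws, dims=first.dims, visit_pair=first.visit_pair, subjects=subjects
    )


def posterior_predict(
    draws: PosteriorDraws, alpha: float = 0.05
) -> tuple[np.ndarray, BandResult]:
    """Predictive means and multiplicity-adjusted intervals for holdouts.

    Uses the per-draw predictive values (fitted mean plus a Gaussian
    noise draw) accumulated during the MCMC run for the registered
    holdout targets, and builds one simultaneous band across the whole
    target set.
    """
    if draws.predictive is None:
        raise ValueError("run the sampler with predict_targets to enable prediction")
    band = mdev_bands(draws.predictive, alpha)
    pred_mean = draws.predictive.mean(axis=0)
    return pred_mean, band
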