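"""Longitudinal tensor response regression model: data, priors, mean structure.

The observation model for subject ``i`` at visit ``t`` (follow-up time
``T_ti``, with ``T_0i = 0``) is

    Y_ti = M + B_i + Gamma * T_ti + Theta_i * T_ti
           + sum_m B_tm * c_im + sum_s D_s * x_is + sum_q C_q * z_tiq + E_ti,

where every coefficient is a rank-R CP tensor and the residuals are
i.i.d. N(0, sigma2) over observed voxels.  ``c_i`` are covariates with
*time-varying* effects (a separate coefficient ``B_tm`` per visit),
``x_i`` are time-invariant covariates, and ``z_ti`` are time-varying
covariates with time-invariant effects.

Each margin vector ``u_{d,r}`` of each coefficient carries a spatially
correlated Gaussian prior N(0, tau * W_{d,r}) with

    W_{d,r} = w_{d,r} * Lambda(alpha_{d,r}),
    Lambda[k1, k2] = exp(-alpha * (k1 - k2)^2),

a squared-exponential kernel on the 1-D margin grid.  Note that the
covariance is taken elementwise as ``w * exp(-alpha d^2)`` (single factor
of ``w``), which is the form under which the closed-form coefficient
covariance ``sum_r w1 w2 w3 exp(-alpha_1 d^2)`` holds exactly.  The
hierarchy is completed by ``w ~ Exp(lambda/2)``, ``lambda ~
Gamma(a_l, b_l)``, ``alpha ~ Gamma(a_a, b_a)``, a Gamma prior on the
precision ``1/tau`` (one tau per coefficient), and ``sigma2 ~
IG(a_e, b_e)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tensor_core import CPTensor, VoxelGrid, reconstruct

__all__ = [
    "StudyData",
    "ModelConfig",
    "PriorHyperparams",
    "FamilySpec",
    "FamilyState",
    "ModelState",
    "build_correlation",
    "build_margin_covariance",
    "build_families",
    "mean_tensor",
    "prior_coefficient_covariance",
]


@dataclass
class StudyData:
    """Outcomes and covariates for a longitudinal imaging study.

    Observations (subject-visit pairs) are stored flat along the first
    axis; subjects may have different numbers of visits.  Voxels outside
    the per-observation mask are ignored by the likelihood (subject- or
    visit-specific missingness, lesions, and prediction holdouts are all
    expressed through the mask).
    """

    grid: VoxelGrid
    subject_of_obs: np.ndarray  # (A,) int, subject index 0..n-1
    visit_of_obs: np.ndarray  # (A,) int
    times: np.ndarray  # (A,) float, days/units since baseline
    Y: np.ndarray  # (A, p1, p2, p3)
    obs_mask: np.ndarray  # (A, p1, p2, p3) bool
    C: np.ndarray  # (n, M) covariates with time-varying effects
    X: np.ndarray  # (n, S) time-invariant covariates
    Z: np.ndarray  # (A, Q) time-varying covariates

    def __post_init__(self) -> None:
        self.subject_of_obs = np.asarray(self.subject_of_obs, dtype=int)
        self.visit_of_obs = np.asarray(self.visit_of_obs, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        self.obs_mask = np.asarray(self.obs_mask, dtype=bool)
        A = self.n_obs
        if self.Y.shape != (A, *self.grid.dims):
            raise ValueError("Y shape does not match grid/observations")
        if self.obs_mask.shape != self.Y.shape:
            raise ValueError("obs_mask shape does not match Y")
        for i in range(self.n_subjects):
            rows = self.subject_of_obs == i
            if not rows.any():
                raise ValueError(f"subject {i} has no visits")
            t0 = self.times[rows][np.argmin(self.visit_of_obs[rows])]
            if self.visit_of_obs[rows].min() == 0 and abs(t0) > 1e-9:
                raise ValueError(f"baseline time for subject {i} must be 0, got {t0}")

    @property
    def n_obs(self) -> int:
        return len(self.subject_of_obs)

    @property
    def n_subjects(self) -> int:
        return int(self.subject_of_obs.max()) + 1

    @property
    def n_visits(self) -> int:
        return int(self.visit_of_obs.max()) + 1

    @property
    def M(self) -> int:
        return self.C.shape[1]

    @property
    def S(self) -> int:
        return self.X.shape[1]

    @property
    def Q(self) -> int:
        return self.Z.shape[1]

    def obs_index(self, subject: int, visit: int) -> int:
        hits = np.flatnonzero(
            (self.subject_of_obs == subject) & (self.visit_of_obs == visit)
        )
        if len(hits) != 1:
            raise KeyError(f"no unique observation for subject {subject}, visit {visit}")
        return int(hits[0])


@dataclass
class ModelConfig:
    """Which terms of the longitudinal model are active.

    ``mode='cross_sectional'`` drops the subject intercepts, population
    and subject slopes, and collapses the per-visit coefficients ``B_tm``
    to a single time-invariant effect per covariate (visits treated as
    exchangeable).
    """

    rank: int = 2
    include_intercept: bool = True
    include_subject_intercept: bool = True
    include_population_slope: bool = True
    include_subject_slope: bool = True
    mode: str = "longitudinal"  # or "cross_sectional"

    def __post_init__(self) -> None:
        if self.mode not in ("longitudinal", "cross_sectional"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "cross_sectional":
            self.include_subject_intercept = False
            self.include_population_slope = False
            self.include_subject_slope = False
        if self.rank < 1:
            raise ValueError("rank must be >= 1")


@dataclass
class PriorHyperparams:
    """Hyperparameters of the shrinkage/smoothing prior hierarchy.

    All pairs are (shape, rate) of Gamma distributions; ``sigma_alpha2``
    is the variance of the log-normal random-walk proposal for the
    lengthscales.  Defaults are weakly informative at unit scale, which
    is appropriate after covariate standardization.
    """

    a_tau: float = 1.0
    b_tau: float = 1.0
    a_eps: float = 1.0
    b_eps: float = 1.0
    a_lam: float = 1.0
    b_lam: float = 1.0
    a_alpha: float = 1.0
    b_alpha: float = 1.0
    sigma_alpha2: float = 0.1

    def __post_init__(self) -> None:
        for name in ("a_tau", "b_tau", "a_eps", "b_eps", "a_lam", "b_lam",
                     "a_alpha", "b_alpha", "sigma_alpha2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def build_correlation(alpha: float, p: int) -> np.ndarray:
    """Squared-exponential correlation ``Lambda[k1,k2] = exp(-alpha (k1-k2)^2)``."""
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    if p < 1:
        raise ValueError("p must be >= 1")
    k = np.arange(p)
    return np.exp(-alpha * (k[:, None] - k[None, :]) ** 2)


def build_margin_covariance(w: float, alpha: float, p: int) -> np.ndarray:
    """Margin prior covariance ``W = w * Lambda(alpha, p)``."""
    if w <= 0:
        raise ValueError("w must be strictly positive")
    return w * build_correlation(alpha, p)


def prior_coefficient_covariance(
    w: np.ndarray, alpha_mode: np.ndarray, displacement: int
) -> float:
    """Closed-form prior covariance between two coefficient entries.

    For voxels ``(k1,k2,k3)`` and ``(k1*,k2,k3)`` differing only along one
    mode by ``displacement = k1 - k1*``, the covariance induced by the
    margin priors is ``sum_r w_{1,r} w_{2,r} w_{3,r} *
    exp(-alpha_{1,r} displacement^2)`` where mode 1 denotes the displaced
    mode.

    Parameters
    ----------
    w
        Array (3, R) of margin variances, displaced mode first.
    alpha_mode
        Array (R,) of lengthscales for the displaced mode.
    """
    w = np.asarray(w, dtype=float)
    alpha_mode = np.asarray(alpha_mode, dtype=float)
    if w.ndim != 2 or w.shape[0] != 3:
        raise ValueError("w must have shape (3, R)")
    return float(
        np.sum(np.prod(w, axis=0) * np.exp(-alpha_mode * displacement**2))
    )


# ---------------------------------------------------------------------------
# Coefficient families
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilySpec:
    """One coefficient tensor of the model and its per-observation loading.

    ``h[a]`` multiplies the reconstructed tensor in the mean of
    observation ``a``; e.g. ``h = T_ti`` for the population slope, an
    indicator of subject ``i`` for a subject intercept, and
    ``c_im * 1[visit == t]`` for a time-varying covariate effect.
    """

    key: str
    kind: str  # one of M, B, Gamma, Theta, Bt, D, C
    h: tuple  # immutable per-observation loading

    @property
    def loading(self) -> np.ndarray:
        return np.asarray(self.h, dtype=float)


def build_families(config: ModelConfig, data: StudyData) -> list[FamilySpec]:
    """Enumerate active coefficient families in the fixed model order."""
    A = data.n_obs
    subj = data.subject_of_obs
    visit = data.visit_of_obs
    fams: list[FamilySpec] = []

    def add(key: str, kind: str, h: np.ndarray) -> None:
        fams.append(FamilySpec(key, kind, tuple(np.asarray(h, dtype=float))))

    if config.include_intercept:
        add("M", "M", np.ones(A))
    if config.include_subject_intercept:
        for i in range(data.n_subjects):
            add(f"B[{i}]", "B", (subj == i).astype(float))
    if config.include_population_slope:
        add("Gamma", "Gamma", data.times)
    if config.include_subject_slope:
        for i in range(data.n_subjects):
            add(f"Theta[{i}]", "Theta", data.times * (subj == i))
    for m in range(data.M):
        if config.mode == "cross_sectional":
            add(f"Bt[{m}]", "Bt", data.C[subj, m])
        else:
            for t in range(data.n_visits):
                add(f"Bt[{t},{m}]", "Bt", data.C[subj, m] * (visit == t))
    for s in range(data.S):
        add(f"D[{s}]", "D", data.X[subj, s])
    for q in range(data.Q):
        add(f"C[{q}]", "C", data.Z[:, q])
    return fams


@dataclass
class FamilyState:
    """Sampler state for one coefficient family: CP margins plus scales."""

    cp: CPTensor
    w: np.ndarray  # (3, R) margin variances
    lam: np.ndarray  # (3, R) exponential rates for w
    alpha: np.ndarray  # (3, R) lengthscales
    tau: float  # global scale of this coefficient

    def copy(self) -> "FamilyState":
        return FamilyState(self.cp.copy(), self.w.copy(), self.lam.copy(),
                           self.alpha.copy(), self.tau)


@dataclass
class ModelState:
    """Complete MCMC state: all family states plus the residual variance."""

    families: dict[str, FamilyState]
    sigma2: float

    def copy(self) -> "ModelState":
        return ModelState({k: f.copy() for k, f in self.families.items()}, self.sigma2)


def mean_tensor(
    state: ModelState,
    data: StudyData,
    subject: int,
    visit: int,
    families: list[FamilySpec] | None = None,
    config: ModelConfig | None = None,
) -> np.ndarray:
    """Model mean for one (subject, visit), reconstructed from CP form."""
    if families is None:
        if config is None:
            raise ValueError("provide either families or config")
        families = build_families(config, data)
    a = data.obs_index(subject, visit)
    out = np.zeros(data.grid.dims)
    for fam in families:
        h = fam.loading[a]
        if h != 0.0:
            out += h * reconstruct(state.families[fam.key].cp)
    return out
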