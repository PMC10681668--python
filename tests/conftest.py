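import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_cp(rng, dims, rank, weights=None):
    from btrr.tensor_core import CPTensor

    margins = [rng.standard_normal((p, rank)) for p in dims]
    return CPTensor(dims, margins, weights)


def brute_force_cp(t):
    """Triple-nested-loop evaluation of the CP element formula."""
    p1, p2, p3 = t.dims
    out = np.zeros(t.dims)
    u1, u2, u3 = t.margins
    for j1 in range(p1):
        for j2 in range(p2):
            for j3 in range(p3):
                out[j1, j2, j3] = sum(
                    t.weights[r] * u1[j1, r] * u2[j2, r] * u3[j3, r]
                    for r in range(t.rank)
                )
    return out


def tiny_study(rng, dims=(3, 3, 3), n_subjects=2, n_visits=2, M=1, S=1, Q=1,
               mask=None):
    """A small fully observed study with standard-normal covariates."""
    from btrr.model import StudyData
    from btrr.tensor_core import VoxelGrid

    A = n_subjects * n_visits
    subj = np.repeat(np.arange(n_subjects), n_visits)
    visit = np.tile(np.arange(n_visits), n_subjects)
    if mask is None:
        mask = np.ones((A, *dims), dtype=bool)
    return StudyData(
        grid=VoxelGrid(dims),
        subject_of_obs=subj,
        visit_of_obs=visit,
        times=visit.astype(float),
        Y=rng.standard_normal((A, *dims)),
        obs_mask=mask,
        C=(rng.random((n_subjects, M)) < 0.5).astype(float),
        X=rng.standard_normal((n_subjects, S)),
        Z=rng.standard_normal((A, Q)),
    )
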