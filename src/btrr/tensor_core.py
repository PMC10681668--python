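"""Rank-R PARAFAC (CP) representation of 3-D coefficient tensors.

A mode-3 tensor ``X`` of shape ``(p1, p2, p3)`` is stored as a sum of R
outer products of per-mode *margin* vectors,

    X[j1, j2, j3] = sum_r  lambda_r * u1[j1, r] * u2[j2, r] * u3[j3, r],

which reduces the parameter count from ``p1*p2*p3`` to ``R*(p1+p2+p3)``.
The margins are identifiable only up to channel permutations and
compensating rescalings; the reconstructed tensor is what the model cares
about, so no identifiability constraint is imposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "CPTensor",
    "VoxelGrid",
    "reconstruct",
    "parameter_count",
    "dense_parameter_count",
    "extract_slice",
    "extract_fiber",
]


@dataclass
class CPTensor:
    """A rank-R CP tensor: three margin matrices plus per-channel weights.

    Parameters
    ----------
    dims
        Tensor extents ``(p1, p2, p3)``.
    margins
        List of three arrays of shape ``(p_d, R)``.
    weights
        Length-R channel weights ``lambda_r``; default all ones.  The
        regression model absorbs scale into the margins and keeps these
        fixed at 1, but they are retained for generality.
    """

    dims: tuple[int, int, int]
    margins: list[np.ndarray]
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dims = tuple(int(p) for p in self.dims)
        if len(self.dims) != 3 or any(p < 1 for p in self.dims):
            raise ValueError(f"dims must be three positive integers, got {self.dims}")
        if len(self.margins) != 3:
            raise ValueError("expected exactly three margin matrices")
        self.margins = [np.asarray(m, dtype=float) for m in self.margins]
        ranks = {m.shape[1] for m in self.margins}
        if len(ranks) != 1:
            raise ValueError("margins disagree on the number of channels R")
        for d, m in enumerate(self.margins):
            if m.ndim != 2 or m.shape[0] != self.dims[d]:
                raise ValueError(
                    f"margin {d} has shape {m.shape}, expected ({self.dims[d]}, R)"
                )
        if self.weights is None:
            self.weights = np.ones(self.rank)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (self.rank,):
                raise ValueError("weights must have length R")

    @property
    def rank(self) -> int:
        return self.margins[0].shape[1]

    @classmethod
    def zeros(cls, dims: tuple[int, int, int], rank: int) -> "CPTensor":
        return cls(dims, [np.zeros((p, rank)) for p in dims])

    def to_dense(self) -> np.ndarray:
        return reconstruct(self)

    def copy(self) -> "CPTensor":
        return CPTensor(self.dims, [m.copy() for m in self.margins], self.weights.copy())

    # -- HDF5 checkpointing -------------------------------------------------
    def to_hdf5(self, group: h5py.Group) -> None:
        group.attrs["dims"] = self.dims
        group.attrs["rank"] = self.rank
        group.create_dataset("weights", data=self.weights)
        for d, m in enumerate(self.margins):
            group.create_dataset(f"margin{d}", data=m)

    @classmethod
    def from_hdf5(cls, group: h5py.Group) -> "CPTensor":
        dims = tuple(int(p) for p in group.attrs["dims"])
        margins = [group[f"margin{d}"][...] for d in range(3)]
        return cls(dims, margins, group["weights"][...])


def reconstruct(t: CPTensor) -> np.ndarray:
    """Evaluate the dense tensor: ``sum_r w_r u1[:,r] o u2[:,r] o u3[:,r]``."""
    u1, u2, u3 = t.margins
    return np.einsum("ir,jr,kr,r->ijk", u1, u2, u3, t.weights, optimize=True)


def parameter_count(dims: tuple[int, int, int], rank: int) -> int:
    """Number of free margin parameters, ``R * (p1 + p2 + p3)``."""
    if rank < 1 or any(int(p) < 1 for p in dims):
        raise ValueError("dims and rank must be positive")
    return int(rank) * int(sum(dims))


def dense_parameter_count(dims: tuple[int, int, int]) -> int:
    """The unstructured alternative, ``p1 * p2 * p3``, for comparison."""
    if any(int(p) < 1 for p in dims):
        raise ValueError("dims must be positive")
    return int(np.prod([int(p) for p in dims]))


def _as_dense(t: CPTensor | np.ndarray) -> np.ndarray:
    if isinstance(t, CPTensor):
        return reconstruct(t)
    return np.asarray(t)


def extract_slice(t: CPTensor | np.ndarray, mode: int, index: int) -> np.ndarray:
    """2-D slice obtained by fixing ``mode`` (1, 2 or 3) at ``index`` (0-based)."""
    x = _as_dense(t)
    if mode not in (1, 2, 3):
        raise ValueError("mode must be 1, 2 or 3")
    if not 0 <= index < x.shape[mode - 1]:
        raise IndexError(f"index {index} out of range for mode {mode}")
    return np.take(x, index, axis=mode - 1)


def extract_fiber(
    t: CPTensor | np.ndarray, mode: int, fixed: tuple[int, int]
) -> np.ndarray:
    """1-D fiber along ``mode``, with the other two indices fixed (0-based)."""
    x = _as_dense(t)
    if mode not in (1, 2, 3):
        raise ValueError("mode must be 1, 2 or 3")
    other = [a for a in range(3) if a != mode - 1]
    ja, jb = fixed
    if not (0 <= ja < x.shape[other[0]] and 0 <= jb < x.shape[other[1]]):
        raise IndexError(f"fiber index {fixed} out of range for mode {mode}")
    idx: list[object] = [slice(None)] * 3
    idx[other[0]] = ja
    idx[other[1]] = jb
    return x[tuple(idx)]


@dataclass
class VoxelGrid:
    """A regular voxel lattice with per-subject observed-voxel sets.

    Linear indices are 0-based and column-major over ``(j1, j2, j3)``, i.e.
    ``lin = j1 + p1 * (j2 + p2 * j3)``; the convention is fixed so indices
    are stable across modules and on-disk artifacts.
    """

    dims: tuple[int, int, int]
    observed: dict[object, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dims = tuple(int(p) for p in self.dims)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    def linear_index(self, triplet: np.ndarray) -> np.ndarray:
        """Map ``(j1, j2, j3)`` triplets (last axis) to linear indices."""
        j = np.asarray(triplet)
        p1, p2, _ = self.dims
        return j[..., 0] + p1 * (j[..., 1] + p2 * j[..., 2])

    def triplet_index(self, linear: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`linear_index`; returns triplets on the last axis."""
        lin = np.asarray(linear)
        p1, p2, _ = self.dims
        j1 = lin % p1
        j2 = (lin // p1) % p2
        j3 = lin // (p1 * p2)
        return np.stack([j1, j2, j3], axis=-1)
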