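"""Data ingestion, voxel screening, and on-disk artifacts.

Real-data mode reads one NIfTI volume per (subject, visit) plus optional
per-subject binary masks and a covariate table (CSV), assembles a
:class:`~btrr.model.StudyData` on the native voxel lattice (no
resampling; registration belongs to preprocessing), and screens out
redundant voxels: those outside the brain mask, inside per-subject
lesion masks, or with near-zero values across every image.  Replicates
and posterior draws persist to HDF5; significance maps and band
endpoints can be written back as NIfTI volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .inference import BandResult
from .model import StudyData
from .sampler import PosteriorDraws
from .simulate import SchemeSpec, SyntheticReplicate
from .tensor_core import VoxelGrid

__all__ = [
    "ScreeningReport",
    "load_study",
    "screen_voxels",
    "save_nifti",
    "write_band_volumes",
    "save_replicate",
    "load_replicate",
    "save_draws",
    "load_draws",
]


# ---------------------------------------------------------------------------
# NIfTI ingestion
# ---------------------------------------------------------------------------

def _read_volume(path, expect_shape=None, expect_affine=None, atol=1e-4):
    img = nib.load(str(path))
    vol = np.asarray(img.get_fdata(), dtype=float)
    if vol.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {vol.shape}")
    if expect_shape is not None and vol.shape != expect_shape:
        raise ValueError(f"{path}: grid {vol.shape} != {expect_shape}")
    if expect_affine is not None and not np.allclose(
        img.affine, expect_affine, atol=atol
    ):
        raise ValueError(f"{path}: affine mismatch")
    return vol, img.affine


def load_study(
    images: dict[tuple[object, int], object],
    covariates: pd.DataFrame | str | Path,
    roles: dict[str, list[str]] | None = None,
    masks: dict[object, object] | None = None,
    standardize: bool = True,
) -> tuple[StudyData, np.ndarray, list[object]]:
    """Assemble a study from NIfTI volumes and a covariate table.

    Parameters
    ----------
    images
        Mapping ``(subject_id, visit) -> NIfTI path``.
    covariates
        Table (or CSV path) with columns ``subject_id``, ``visit``,
        ``time_days``, plus named covariates.
    roles
        ``{"c": [...], "x": [...], "z": [...]}`` column names mapped to
        time-varying-effect, time-invariant, and time-varying covariates.
    masks
        Optional ``subject_id -> binary NIfTI path`` observed-voxel masks.
    standardize
        z-score continuous covariate columns (binary 0/1 columns are
        left untouched).

    Returns
    -------
    (study, affine, subject_ids); the affine is carried through so
    outputs can be written back in register.
    """
    if not isinstance(covariates, pd.DataFrame):
        covariates = pd.read_csv(covariates)
    required = {"subject_id", "visit", "time_days"}
    if not required <= set(covariates.columns):
        raise ValueError(f"covariate table must contain columns {sorted(required)}")
    roles = roles or {"c": [], "x": [], "z": []}
    df = covariates.sort_values(["subject_id", "visit"]).reset_index(drop=True)
    subject_ids = list(dict.fromkeys(df["subject_id"]))
    sub_index = {s: i for i, s in enumerate(subject_ids)}

    for s, g in df.groupby("subject_id"):
        if (g["visit"] == 0).any():
            t0 = float(g.loc[g["visit"] == 0, "time_days"].iloc[0])
            if abs(t0) > 1e-9:
                raise ValueError(f"subject {s}: baseline time_days must be 0, got {t0}")
        if not g["time_days"].is_monotonic_increasing:
            raise ValueError(f"subject {s}: times must be non-decreasing in visit")

    first = next(iter(images.values()))
    vol0, affine = _read_volume(first)
    shape = vol0.shape
    A = len(df)
    Y = np.zeros((A, *shape))
    for a, row in df.iterrows():
        key = (row["subject_id"], int(row["visit"]))
        if key not in images:
            raise ValueError(f"missing image for subject {key[0]} visit {key[1]}")
        Y[a], _ = _read_volume(images[key], shape, affine)

    obs = np.ones((A, *shape), dtype=bool)
    if masks:
        subj_mask = {}
        for s, path in masks.items():
            m, _ = _read_volume(path, shape, affine)
            subj_mask[s] = m > 0.5
        for a, row in df.iterrows():
            if row["subject_id"] in subj_mask:
                obs[a] = subj_mask[row["subject_id"]]

    def pull(cols, per_subject):
        if per_subject:
            base = df.drop_duplicates("subject_id").set_index("subject_id")
            return np.column_stack(
                [base.loc[subject_ids, c].to_numpy(dtype=float) for c in cols]
            ) if cols else np.zeros((len(subject_ids), 0))
        return np.column_stack(
            [df[c].to_numpy(dtype=float) for c in cols]
        ) if cols else np.zeros((A, 0))

    C = pull(roles.get("c", []), per_subject=True)
    X = pull(roles.get("x", []), per_subject=True)
    Z = pull(roles.get("z", []), per_subject=False)
    if standardize:
        for arr in (C, X, Z):
            for j in range(arr.shape[1]):
                col = arr[:, j]
                if set(np.unique(col)) <= {0.0, 1.0}:
                    continue  # binary covariates stay 0/1
                arr[:, j] = (col - col.mean()) / col.std(ddof=0)

    study = StudyData(
        grid=VoxelGrid(shape),
        subject_of_obs=df["subject_id"].map(sub_index).to_numpy(),
        visit_of_obs=df["visit"].to_numpy(dtype=int),
        times=df["time_days"].to_numpy(dtype=float),
        Y=Y,
        obs_mask=obs,
        C=C,
        X=X,
        Z=Z,
    )
    return study, affine, subject_ids


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

@dataclass
class ScreeningReport:
    """Counts of voxels removed by each redundancy rule, in order."""

    n_voxels: int
    removed_outside_mask: int
    removed_near_zero: int
    lesion_removed_per_subject: dict[int, int] = field(default_factory=dict)
    observed_per_subject: dict[int, int] = field(default_factory=dict)

    @property
    def remaining(self) -> int:
        return self.n_voxels - self.removed_outside_mask - self.removed_near_zero


def screen_voxels(
    study: StudyData,
    near_zero_threshold: float = 1e-6,
    lesion_masks: dict[int, np.ndarray] | None = None,
    brain_mask: np.ndarray | None = None,
) -> tuple[StudyData, ScreeningReport]:
    """Drop redundant voxels; returns the filtered study and a report.

    Rules, applied in order: (i) voxels outside the brain mask (default:
    observed for no subject) are removed globally; (ii) per-subject
    lesion voxels are removed from that subject's observed set only;
    (iii) voxels whose values are within ``near_zero_threshold`` of zero
    in *every* image are removed globally.  The operation is idempotent.
    """
    if near_zero_threshold < 0:
        raise ValueError("near-zero threshold must be non-negative")
    mask = study.obs_mask.copy()
    if brain_mask is None:
        brain = mask.any(axis=0)
    else:
        brain = np.asarray(brain_mask, dtype=bool)
    n_out = int((~brain).sum())
    mask &= brain[None]

    lesion_counts = {}
    if lesion_masks:
        for i, les in lesion_masks.items():
            les = np.asarray(les, dtype=bool)
            rows = np.flatnonzero(study.subject_of_obs == i)
            before = mask[rows].sum()
            mask[rows] &= ~les[None]
            lesion_counts[i] = int((before - mask[rows].sum()) // max(len(rows), 1))

    near_zero = (np.abs(study.Y) <= near_zero_threshold).all(axis=0) & brain
    n_near = int(near_zero.sum())
    mask &= ~near_zero[None]

    filtered = StudyData(
        grid=study.grid,
        subject_of_obs=study.subject_of_obs,
        visit_of_obs=study.visit_of_obs,
        times=study.times,
        Y=study.Y,
        obs_mask=mask,
        C=study.C,
        X=study.X,
        Z=study.Z,
    )
    per_subject = {
        i: int(mask[np.flatnonzero(study.subject_of_obs == i)[0]].sum())
        for i in range(study.n_subjects)
    }
    report = ScreeningReport(
        n_voxels=study.grid.n_voxels,
        removed_outside_mask=n_out,
        removed_near_zero=n_near,
        lesion_removed_per_subject=lesion_counts,
        observed_per_subject=per_subject,
    )
    return filtered, report


# ---------------------------------------------------------------------------
# NIfTI / HDF5 outputs
# ---------------------------------------------------------------------------

def save_nifti(volume: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32),
                             affine if affine is not None else np.eye(4)), str(path))


def write_band_volumes(
    band: BandResult,
    dims: tuple[int, int, int],
    out_prefix,
    affine: np.ndarray | None = None,
) -> dict:
    """Write significance (+1/0/-1) and band-endpoint volumes as NIfTI."""
    out_prefix = Path(out_prefix)
    sig = np.zeros(len(band.mean))
    sig[band.significant & (band.mean > 0)] = 1.0
    sig[band.significant & (band.mean < 0)] = -1.0
    paths = {}
    for name, arr in [
        ("significance", sig),
        ("lower", band.lower),
        ("upper", band.upper),
        ("mean", band.mean),
    ]:
        p = out_prefix.parent / f"{out_prefix.name}_{name}.nii.gz"
        save_nifti(arr.reshape(dims), p, affine)
        paths[name] = p
    return paths


def save_replicate(rep: SyntheticReplicate, path) -> None:
    with h5py.File(path, "w") as f:
        d = rep.data
        g = f.create_group("data")
        g.attrs["dims"] = d.grid.dims
        g.create_dataset("subject_of_obs", data=d.subject_of_obs, track_times=False)
        g.create_dataset("visit_of_obs", data=d.visit_of_obs, track_times=False)
        g.create_dataset("times", data=d.times, track_times=False)
        g.create_dataset("Y", data=d.Y, track_times=False)
        g.create_dataset("obs_mask", data=d.obs_mask, track_times=False)
        g.create_dataset("C", data=d.C, track_times=False)
        g.create_dataset("X", data=d.X, track_times=False)
        g.create_dataset("Z", data=d.Z, track_times=False)
        t = f.create_group("truth")
        for k, v in rep.truth.items():
            t.create_dataset(k, data=v, track_times=False)
        f.create_dataset("signal", data=rep.signal, track_times=False)
        f.attrs["sigma2"] = rep.sigma2
        for name in ("scheme", "n_subjects", "n_visits", "snr", "rank",
                     "margin_zero_prob", "shape_zero_fraction", "seed"):
            f.attrs[name] = getattr(rep.spec, name)
        f.attrs["dims"] = rep.spec.dims
        f.attrs["tv_zero_schedule"] = rep.spec.tv_zero_schedule
        if rep.spec.holdout_fraction is not None:
            f.attrs["holdout_fraction"] = rep.spec.holdout_fraction
        if rep.holdout_targets is not None:
            f.create_dataset("holdout/targets", data=rep.holdout_targets, track_times=False)
            f.create_dataset("holdout/truth", data=rep.holdout_truth, track_times=False)
            f.create_dataset("holdout/observed", data=rep.holdout_observed, track_times=False)


def load_replicate(path) -> SyntheticReplicate:
    with h5py.File(path, "r") as f:
        g = f["data"]
        data = StudyData(
            grid=VoxelGrid(tuple(g.attrs["dims"])),
            subject_of_obs=g["subject_of_obs"][...],
            visit_of_obs=g["visit_of_obs"][...],
            times=g["times"][...],
            Y=g["Y"][...],
            obs_mask=g["obs_mask"][...].astype(bool),
            C=g["C"][...],
            X=g["X"][...],
            Z=g["Z"][...],
        )
        spec = SchemeSpec(
            scheme=str(f.attrs["scheme"]),
            dims=tuple(int(x) for x in f.attrs["dims"]),
            n_subjects=int(f.attrs["n_subjects"]),
            n_visits=int(f.attrs["n_visits"]),
            snr=float(f.attrs["snr"]),
            rank=int(f.attrs["rank"]),
            margin_zero_prob=float(f.attrs["margin_zero_prob"]),
            shape_zero_fraction=float(f.attrs["shape_zero_fraction"]),
            tv_zero_schedule=tuple(f.attrs["tv_zero_schedule"]),
            holdout_fraction=(
                float(f.attrs["holdout_fraction"]) if "holdout_fraction" in f.attrs
                else None
            ),
            seed=int(f.attrs["seed"]),
        )
        rep = SyntheticReplicate(
            data=data,
            truth={k: f["truth"][k][...] for k in f["truth"]},
            signal=f["signal"][...],
            sigma2=float(f.attrs["sigma2"]),
            spec=spec,
        )
        if "holdout" in f:
            rep.holdout_targets = f["holdout/targets"][...]
            rep.holdout_truth = f["holdout/truth"][...]
            rep.holdout_observed = f["holdout/observed"][...]
    return rep


def save_draws(draws: PosteriorDraws, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["family_keys"] = draws.family_keys
        f.attrs["n_obs_voxels"] = draws.n_obs_voxels
        g = f.create_group("coef_draws")
        for k, v in draws.coef_draws.items():
            g.create_dataset(k, data=v, chunks=(1, *v.shape[1:]), track_times=False)
        m = f.create_group("coef_mean")
        for k, v in draws.coef_mean.items():
            m.create_dataset(k, data=v, track_times=False)
        f.create_dataset("sigma2", data=draws.sigma2, track_times=False)
        f.create_dataset("deviance", data=draws.deviance, track_times=False)
        f.create_dataset("tau_trace", data=draws.tau_trace, track_times=False)
        acc = f.create_group("alpha_accept")
        for k, v in draws.alpha_accept.items():
            acc.create_dataset(k, data=v, track_times=False)
        if draws.predictive is not None:
            f.create_dataset("predict/targets", data=draws.predict_targets, track_times=False)
            f.create_dataset("predict/draws", data=draws.predictive, track_times=False)
            f.create_dataset("predict/mean", data=draws.predictive_mean, track_times=False)
        if draws.fitted_trace is not None:
            f.create_dataset("fitted_trace", data=draws.fitted_trace, track_times=False)


def load_draws(path) -> PosteriorDraws:
    with h5py.File(path, "r") as f:
        draws = PosteriorDraws(
            family_keys=[str(k) for k in f.attrs["family_keys"]],
            coef_draws={k: f["coef_draws"][k][...] for k in f["coef_draws"]},
            coef_mean={k: f["coef_mean"][k][...] for k in f["coef_mean"]},
            sigma2=f["sigma2"][...],
            deviance=f["deviance"][...],
            tau_trace=f["tau_trace"][...],
            alpha_accept={k: f["alpha_accept"][k][...] for k in f["alpha_accept"]},
            n_obs_voxels=int(f.attrs["n_obs_voxels"]),
        )
        if "predict" in f:
            draws.predict_targets = f["predict/targets"][...]
            draws.predictive = f["predict/draws"][...]
            draws.predictive_mean = f["predict/mean"][...]
        if "fitted_trace" in f:
            draws.fitted_trace = f["fitted_trace"][...]
    return draws
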