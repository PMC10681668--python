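"""Performance metrics for the simulation study.

Out-of-sample prediction error (p-RMSE) and correlation (p-Corr) over
pooled holdout voxels, coefficient recovery error (c-RMSE), selection
sensitivity / specificity / precision / F1 against the true nonzero
mask, and coverage / mean width of predictive intervals against the
noise-free truth.  Undefined quantities (correlation of a constant
vector, sensitivity with an empty truth) are reported as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "MetricReport",
    "prediction_metrics",
    "coefficient_rmse",
    "selection_metrics",
    "coverage_metrics",
]


@dataclass
class MetricReport:
    """One row of simulation results for one replicate and method."""

    replicate: int = -1
    method: str = "l-BTRR"
    p_rmse: float = np.nan
    p_corr: float = np.nan
    c_rmse: float = np.nan
    sensitivity: float = np.nan
    specificity: float = np.nan
    precision: float = np.nan
    f1: float = np.nan
    coverage: float = np.nan
    interval_width: float = np.nan
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {
            "replicate": self.replicate,
            "method": self.method,
            "p_rmse": self.p_rmse,
            "p_corr": self.p_corr,
            "c_rmse": self.c_rmse,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1": self.f1,
            "coverage": self.coverage,
            "interval_width": self.interval_width,
        }
        out.update(self.extras)
        return out


def prediction_metrics(predicted: np.ndarray, observed: np.ndarray) -> tuple[float, float]:
    """(RMSE, Pearson r) over pooled holdout predictions."""
    predicted = np.asarray(predicted, dtype=float).ravel()
    observed = np.asarray(observed, dtype=float).ravel()
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed are misaligned")
    rmse = float(np.sqrt(np.mean((predicted - observed) ** 2)))
    if np.ptp(predicted) < 1e-15 or np.ptp(observed) < 1e-15:
        return rmse, float("nan")
    corr = float(stats.pearsonr(predicted, observed).statistic)
    return rmse, corr


def coefficient_rmse(
    true: np.ndarray | dict[str, np.ndarray],
    estimated: np.ndarray | dict[str, np.ndarray],
) -> float:
    """Voxelwise RMSE between true and estimated coefficients.

    Dict inputs are pooled across families (the coefficient-recovery
    summaries average over the covariate-effect tensors).
    """
    if isinstance(true, dict) != isinstance(estimated, dict):
        raise ValueError("true and estimated must both be arrays or both dicts")
    if isinstance(true, dict):
        keys = sorted(true)
        if sorted(estimated) != keys:
            raise ValueError("family keys differ")
        t = np.concatenate([np.ravel(true[k]) for k in keys])
        e = np.concatenate([np.ravel(estimated[k]) for k in keys])
    else:
        t, e = np.ravel(true), np.ravel(estimated)
    if t.shape != e.shape:
        raise ValueError("coefficient shapes differ")
    return float(np.sqrt(np.mean((t - e) ** 2)))


def selection_metrics(
    true_nonzero: np.ndarray, selected: np.ndarray
) -> tuple[float, float, float, float]:
    """(sensitivity, specificity, precision, F1) from boolean masks.

    F1 is the harmonic mean of recall and precision,
    ``2 * recall * precision / (recall + precision)``, set to 0 when both
    are 0 by convention.
    """
    truth = np.asarray(true_nonzero, dtype=bool).ravel()
    sel = np.asarray(selected, dtype=bool).ravel()
    if truth.shape != sel.shape:
        raise ValueError("masks differ in size")
    tp = int(np.sum(truth & sel))
    fp = int(np.sum(~truth & sel))
    fn = int(np.sum(truth & ~sel))
    tn = int(np.sum(~truth & ~sel))
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    prec = tp / (tp + fp) if (tp + fp) else float("nan")
    if np.isnan(sens):
        f1 = float("nan")
    elif tp == 0:
        f1 = 0.0
    else:
        f1 = 2.0 * sens * prec / (sens + prec)
    return sens, spec, prec, f1


def coverage_metrics(
    lower: np.ndarray, upper: np.ndarray, truth: np.ndarray
) -> tuple[float, float]:
    """(coverage fraction, mean interval width) against noise-free truth."""
    lower = np.asarray(lower, dtype=float).ravel()
    upper = np.asarray(upper, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    if not (lower.shape == upper.shape == truth.shape):
        raise ValueError("interval endpoints and truth are misaligned")
    if np.any(upper < lower):
        raise ValueError("inverted interval endpoints")
    covered = (truth >= lower) & (truth <= upper)
    return float(covered.mean()), float(np.mean(upper - lower))
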