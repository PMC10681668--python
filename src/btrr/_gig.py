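"""Vectorized generalized inverse Gaussian sampling.

The margin-variance full conditionals of the model are GIG distributed,

    f(x) propto x^(p-1) exp(-(a x + b / x) / 2),   x > 0,

with order ``p = 1 - p_d/2`` (typically negative).  SciPy's generator is
accurate but slow for the hundreds of scalar draws needed per MCMC sweep,
so draws are produced here by rejection sampling on the log scale:
``Y = log(X / sqrt(b/a))`` has a *log-concave* density proportional to
``exp(p y - omega cosh y)`` with ``omega = sqrt(a b)``, which admits a
simple three-piece (uniform centre + two exponential tails) envelope
built from the points where the log-density drops one unit below its
mode.  Acceptance rates are ~0.6-0.8 across the parameter range.
"""

from __future__ import annotations

import numpy as np

__all__ = ["gig_rvs", "gig_logpdf"]

_DROP = 1.0  # log-density drop defining the envelope knots


def _h(y: np.ndarray, p: np.ndarray, omega: np.ndarray) -> np.ndarray:
    return p * y - omega * np.cosh(y)


def _hprime(y: np.ndarray, p: np.ndarray, omega: np.ndarray) -> np.ndarray:
    return p - omega * np.sinh(y)


def _bracket_root(p, omega, hstar, ystar, direction):
    """Solve h(y) = hstar - _DROP on one side of the mode by bisection."""
    step = np.full_like(ystar, 1.0)
    lo = ystar.copy()
    hi = ystar + direction * step
    # expand until the target level is bracketed
    for _ in range(200):
        not_past = _h(hi, p, omega) > hstar - _DROP
        if not not_past.any():
            break
        step = np.where(not_past, step * 2.0, step)
        hi = np.where(not_past, ystar + direction * step, hi)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        above = _h(mid, p, omega) > hstar - _DROP
        lo = np.where(above, mid, lo)
        hi = np.where(above, hi, mid)
    return 0.5 * (lo + hi)


def gig_rvs(
    p: np.ndarray | float,
    a: np.ndarray | float,
    b: np.ndarray | float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one variate per element from GIG(p, a, b).

    Parameters broadcast; ``a`` and ``b`` must be strictly positive
    (callers should jitter degenerate quadratic forms before calling).
    """
    p, a, b = np.broadcast_arrays(
        np.atleast_1d(np.asarray(p, dtype=float)),
        np.atleast_1d(np.asarray(a, dtype=float)),
        np.atleast_1d(np.asarray(b, dtype=float)),
    )
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("GIG parameters a and b must be strictly positive")
    shape = p.shape
    p, a, b = p.ravel(), a.ravel(), b.ravel()
    omega = np.sqrt(a * b)
    scale = np.sqrt(b / a)

    ystar = np.arcsinh(p / omega)
    hstar = _h(ystar, p, omega)
    yl = _bracket_root(p, omega, hstar, ystar, -1.0)
    yr = _bracket_root(p, omega, hstar, ystar, +1.0)
    sl = _hprime(yl, p, omega)  # > 0
    sr = _hprime(yr, p, omega)  # < 0

    area_c = yr - yl
    area_l = np.exp(-_DROP) / sl
    area_r = np.exp(-_DROP) / (-sr)
    total = area_c + area_l + area_r

    out = np.empty_like(p)
    todo = np.ones(len(p), dtype=bool)
    for _ in range(200):
        idx = np.flatnonzero(todo)
        if len(idx) == 0:
            break
        u = rng.random(len(idx)) * total[idx]
        e = rng.exponential(size=len(idx))
        v = rng.random(len(idx))
        y = np.empty(len(idx))
        log_env = np.empty(len(idx))

        in_c = u < area_c[idx]
        in_l = (~in_c) & (u < (area_c + area_l)[idx])
        in_r = ~(in_c | in_l)
        y[in_c] = yl[idx][in_c] + u[in_c]
        log_env[in_c] = 0.0
        y[in_l] = yl[idx][in_l] - e[in_l] / sl[idx][in_l]
        log_env[in_l] = -_DROP + sl[idx][in_l] * (y[in_l] - yl[idx][in_l])
        y[in_r] = yr[idx][in_r] + e[in_r] / (-sr[idx][in_r])
        log_env[in_r] = -_DROP + sr[idx][in_r] * (y[in_r] - yr[idx][in_r])

        log_ratio = _h(y, p[idx], omega[idx]) - hstar[idx] - log_env
        accept = np.log(v) < log_ratio
        acc_idx = idx[accept]
        out[acc_idx] = y[accept]
        todo[acc_idx] = False
    else:  # pragma: no cover - safeguarded against envelope bugs
        raise RuntimeError("GIG rejection sampler failed to converge")

    return (scale * np.exp(out)).reshape(shape)


def gig_logpdf(x: np.ndarray, p: float, a: float, b: float) -> np.ndarray:
    """Unnormalized log-density, for validation against quadrature."""
    x = np.asarray(x, dtype=float)
    return (p - 1.0) * np.log(x) - 0.5 * (a * x + b / x)
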