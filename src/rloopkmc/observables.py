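"""Reductions of R-loop trajectory ensembles to stability statistics.

All time-fraction observables are time-weighted averages over [0, max_t];
a trajectory absorbed at m = 0 contributes its post-absorption time at
m = 0, which keeps every profile normalized and (deliberately) lowers the
stability metrics of dissociating ensembles.  Replicates are i.i.d., so
standard errors are computed across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .invasion_kmc import (
    ABSORBING,
    RateTable,
    ResidencyEnsemble,
    Trajectory,
    _check_boundary,
    _falloff_ensemble_kernel,
    _first_passage_ensemble_kernel,
    derive_seeds,
)


def _residency_matrix(trajs) -> tuple[np.ndarray, float]:
    """(reps x (N+1) residency matrix, max_t) from either input flavour."""
    if isinstance(trajs, ResidencyEnsemble):
        return trajs.residency, trajs.max_t
    trajs = list(trajs)
    if not trajs:
        raise ValueError("empty trajectory ensemble")
    max_t = trajs[0].max_t
    n = max(t.n_positions for t in trajs)
    if any(abs(t.max_t - max_t) > 1e-12 for t in trajs):
        raise ValueError("trajectories must share a common max_t")
    mat = np.zeros((len(trajs), n + 1))
    for i, tr in enumerate(trajs):
        res = tr.residency_times()
        mat[i, : len(res)] = res
    return mat, max_t


def occupancy_profile(trajs) -> np.ndarray:
    """Mean fraction of [0, max_t] spent at each R-loop length m = 0..N.

    Accepts a list of :class:`Trajectory` or a :class:`ResidencyEnsemble`.
    Entries sum to 1 (absorbed time counted at m = 0).
    """
    mat, max_t = _residency_matrix(trajs)
    return mat.mean(axis=0) / max_t


@dataclass(frozen=True)
class ThresholdOccupancy:
    """Mean fraction of time m >= m_star, with its replicate SEM."""

    m_star: int
    mean_frac: float
    sem: float
    reps: int


def threshold_occupancy(trajs, m_star: int) -> ThresholdOccupancy:
    """Time-average of 1{m(t) >= m_star} over [0, max_t], mean +/- SEM.

    Equals the tail sum of :func:`occupancy_profile` beyond m_star.
    """
    mat, max_t = _residency_matrix(trajs)
    n = mat.shape[1] - 1
    if not 0 <= m_star <= n:
        raise ValueError(f"m_star must be in 0..{n}")
    fracs = mat[:, m_star:].sum(axis=1) / max_t
    reps = len(fracs)
    sem = float(fracs.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0
    return ThresholdOccupancy(
        m_star=int(m_star), mean_frac=float(fracs.mean()), sem=sem, reps=reps
    )


@dataclass(frozen=True)
class StabilityProfile:
    """Threshold occupancies over a ladder of positions m*."""

    thresholds: np.ndarray
    mean_frac: np.ndarray
    sem: np.ndarray
    reps: int
    max_t: float
    m0: int


def stability_profile(trajs, thresholds, m0: int | None = None) -> StabilityProfile:
    mat, max_t = _residency_matrix(trajs)
    rows = [threshold_occupancy(trajs, int(m)) for m in thresholds]
    return StabilityProfile(
        thresholds=np.asarray(list(thresholds), dtype=int),
        mean_frac=np.array([r.mean_frac for r in rows]),
        sem=np.array([r.sem for r in rows]),
        reps=mat.shape[0],
        max_t=max_t,
        m0=-1 if m0 is None else int(m0),
    )


@dataclass(frozen=True)
class LifetimeResult:
    """First-passage times from full invasion to m < m_star.

    ``mean`` is over uncensored replicates only and is NaN if every
    replicate was censored at max_t (reported, not raised).
    """

    mean: float
    sem: float
    times: np.ndarray
    censored_fraction: float
    reps: int

    @property
    def all_censored(self) -> bool:
        return self.censored_fraction >= 1.0


def lifetime_to_below(
    rates: RateTable,
    start_m: int,
    m_star: int,
    reps: int,
    max_t: float,
    seed: int,
    boundary: str = ABSORBING,
) -> LifetimeResult:
    """Per-replicate first time t with m(t) < m_star, starting from start_m."""
    if not start_m > m_star >= 0:
        raise ValueError("need start_m > m_star >= 0")
    n = rates.n_positions
    if start_m > n:
        raise ValueError(f"start_m must be <= {n}")
    absorbing = _check_boundary(boundary)
    fw, rv = rates.full_arrays()
    times = np.empty(reps)
    censored = np.zeros(reps, dtype=np.bool_)
    seeds = derive_seeds(seed, reps)
    _first_passage_ensemble_kernel(
        fw, rv, int(start_m), int(m_star), float(max_t), seeds, absorbing, times, censored
    )
    ok = times[~censored]
    if len(ok):
        mean = float(ok.mean())
        sem = float(ok.std(ddof=1) / np.sqrt(len(ok))) if len(ok) > 1 else 0.0
    else:
        mean = float("nan")
        sem = float("nan")
    return LifetimeResult(
        mean=mean,
        sem=sem,
        times=times[~censored],
        censored_fraction=float(censored.mean()),
        reps=reps,
    )


@dataclass(frozen=True)
class FalloffResult:
    """Binomial estimate of guide fall-off before a stop event."""

    probability: float
    ci_low: float
    ci_high: float
    n_falloff: int
    n_stopped: int
    n_censored: int
    reps: int


def _clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    lo = 0.0 if k == 0 else stats.beta.ppf(alpha / 2, k, n - k + 1)
    hi = 1.0 if k == n else stats.beta.ppf(1 - alpha / 2, k + 1, n - k)
    return float(lo), float(hi)


def falloff_probability(
    rates: RateTable,
    m0: int = 10,
    stop: str = "full_invasion",
    reps: int = 1000,
    max_t: float = 100.0,
    seed: int = 0,
    mismatch_position: int | None = None,
    boundary: str = ABSORBING,
) -> FalloffResult:
    """Fraction of replicates absorbed at m = 0 before the stop event.

    ``stop`` is ``"full_invasion"`` (m reaches N) or ``"past_mismatch"``
    (m reaches ``mismatch_position``, i.e. the mismatch is traversed).
    Exact (Clopper-Pearson) 95% CI on the point estimate.  Only defined for
    the absorbing boundary.
    """
    if not _check_boundary(boundary):
        raise ValueError("falloff_probability requires the absorbing boundary")
    n = rates.n_positions
    if stop == "full_invasion":
        stop_m = n
    elif stop == "past_mismatch":
        if mismatch_position is None:
            raise ValueError("stop='past_mismatch' requires mismatch_position")
        stop_m = int(mismatch_position)
    else:
        raise ValueError(f"unknown stop condition {stop!r}")
    if not 0 <= m0 <= n:
        raise ValueError(f"m0 must be in 0..{n}")
    fw, rv = rates.full_arrays()
    outcomes = np.empty(reps, dtype=np.int64)
    seeds = derive_seeds(seed, reps)
    _falloff_ensemble_kernel(fw, rv, int(m0), stop_m, float(max_t), seeds, outcomes)
    k = int((outcomes == 0).sum())
    lo, hi = _clopper_pearson(k, reps)
    return FalloffResult(
        probability=k / reps,
        ci_low=lo,
        ci_high=hi,
        n_falloff=k,
        n_stopped=int((outcomes == 1).sum()),
        n_censored=int((outcomes == 2).sum()),
        reps=reps,
    )


def retrap_count(traj: Trajectory, p: int) -> int:
    """Number of excursions from m >= p back to m < p after p is first reached.

    Counts "re-trapping" events behind a mismatch at position p;
    0 if the trajectory never reaches p.
    """
    if not 1 <= p <= traj.n_positions:
        raise ValueError(f"p must be in 1..{traj.n_positions}")
    path = traj.state_path()
    above = path >= p
    if not above.any():
        return 0
    first = int(np.argmax(above))
    # count downward crossings of the p boundary after the first arrival
    crossings = np.diff(above[first:].astype(np.int8))
    return int((crossings == -1).sum())
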