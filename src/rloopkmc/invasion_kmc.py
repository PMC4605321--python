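"""Continuous-time, discrete-state (Gillespie) simulation of R-loop dynamics.

The R-loop length m (number of PAM-proximal protospacer positions invaded
by the guide RNA) performs a one-dimensional random walk on 0..N in the
sequence-dependent potential defined by the per-position exchange energies
ddG(m) (see :mod:`rloopkmc.thermo`).  Transition rates, in arbitrary time
units with prefactor k0:

    v_f(m) = k0 * exp(-ddG(m+1) / 2RT)     (m -> m+1, invasion)
    v_r(m) = k0 * exp(+ddG(m)   / 2RT)     (m -> m-1, re-annealing)

The symmetric 1/2 split satisfies detailed balance:
v_f(m)/v_r(m+1) = exp(-ddG(m+1)/RT), so a reflecting chain is Boltzmann
distributed, pi(m) proportional to exp(-G(m)/RT) with G(m) = sum_{j<=m} ddG(j).

The boundary at m = N is reflecting (no forward move at full invasion).
The boundary at m = 0 is configurable: ``absorbing_at_zero`` (default;
reaching 0 models guide fall-off and the walk stops) or
``reflecting_at_zero``.

Simulation kernels are numba-compiled; each trajectory is driven by its own
32-bit seed so ensembles are reproducible replicate-by-replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .thermo import EnergyModel, GuideTargetPair, exchange_energy_profile

ABSORBING = "absorbing_at_zero"
REFLECTING = "reflecting_at_zero"
_BOUNDARIES = (ABSORBING, REFLECTING)

#: guard for exp() overflow in rate construction
_MAX_EXPONENT = 700.0


def _check_boundary(boundary: str) -> bool:
    """Return True for absorbing, False for reflecting; reject junk."""
    if boundary not in _BOUNDARIES:
        raise ValueError(f"boundary must be one of {_BOUNDARIES}, got {boundary!r}")
    return boundary == ABSORBING


@dataclass(frozen=True)
class RateTable:
    """Per-position forward/reverse KMC rates for a chain on 0..N.

    ``v_f[m]`` is the rate of m -> m+1 for m = 0..N-1; ``v_r[m-1]`` the rate
    of m -> m-1 for m = 1..N.  Rates are nonnegative and finite.
    """

    v_f: np.ndarray
    v_r: np.ndarray
    k0: float = 1.0

    def __post_init__(self):
        v_f = np.ascontiguousarray(self.v_f, dtype=np.float64)
        v_r = np.ascontiguousarray(self.v_r, dtype=np.float64)
        object.__setattr__(self, "v_f", v_f)
        object.__setattr__(self, "v_r", v_r)
        if v_f.shape != v_r.shape or v_f.ndim != 1 or len(v_f) == 0:
            raise ValueError("v_f and v_r must be equal-length 1-D vectors")
        for name, v in (("v_f", v_f), ("v_r", v_r)):
            if not np.all(np.isfinite(v)) or np.any(v < 0):
                raise ValueError(f"{name} must be nonnegative and finite")

    @property
    def n_positions(self) -> int:
        return len(self.v_f)

    def full_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Rates indexed by state: (fw[0..N], rv[0..N]) with fw[N]=rv[0]=0."""
        n = self.n_positions
        fw = np.zeros(n + 1)
        rv = np.zeros(n + 1)
        fw[:n] = self.v_f
        rv[1:] = self.v_r
        return fw, rv


def rate_table_from_exchange_energies(
    ddg: np.ndarray, rt: float, k0: float = 1.0
) -> RateTable:
    """Build a :class:`RateTable` from ddG(1..N) (kcal/mol) at thermal energy RT."""
    ddg = np.asarray(ddg, dtype=np.float64)
    args = ddg / (2.0 * rt)
    bad = np.nonzero(np.abs(args) > _MAX_EXPONENT)[0]
    if bad.size:
        raise OverflowError(
            f"|ddG|/(2RT) exceeds {_MAX_EXPONENT:g} at position {bad[0] + 1}"
        )
    return RateTable(v_f=k0 * np.exp(-args), v_r=k0 * np.exp(+args), k0=k0)


def build_rate_table(
    pair: GuideTargetPair, model: EnergyModel, k0: float = 1.0
) -> RateTable:
    """Sequence-dependent rate table for a guide/protospacer pair."""
    ddg = exchange_energy_profile(pair, model)
    return rate_table_from_exchange_energies(ddg, model.rt, k0)


@dataclass(frozen=True)
class Trajectory:
    """A continuous-time state path m(t).

    ``times[0] = 0`` and ``times[i+1]`` is the time of the i-th event, so
    ``len(times) == len(states) + 1``; ``states[i]`` is the R-loop length
    after event i (the walk is at ``m0`` on ``[times[0], times[1])``).  The
    final state is held until ``max_t`` (or, if ``absorbed``, the walk sits
    at 0 from ``absorption_time`` on).
    """

    times: np.ndarray
    states: np.ndarray
    m0: int
    max_t: float
    n_positions: int
    absorbed: bool = False
    absorption_time: float = float("nan")
    seed: int | None = None

    def __post_init__(self):
        if len(self.times) != len(self.states) + 1:
            raise ValueError("times must have exactly one more entry than states")

    def state_path(self) -> np.ndarray:
        """States occupied on each inter-event interval, starting from m0."""
        return np.concatenate([[self.m0], self.states]).astype(np.int64)

    def residency_times(self) -> np.ndarray:
        """Time spent in each state 0..N over [0, max_t] (absorbed time at 0)."""
        out = np.zeros(self.n_positions + 1)
        path = self.state_path()
        edges = np.concatenate([self.times, [self.max_t]])
        if self.absorbed:
            # path already ends at 0; the final hold interval lands there
            pass
        np.add.at(out, path, np.diff(edges))
        return out


# ---------------------------------------------------------------------------
# numba kernels -- one RNG stream per trajectory, seeded explicitly
# ---------------------------------------------------------------------------


@njit(cache=True)
def _traj_kernel(fw, rv, m0, max_t, seed, absorbing):
    np.random.seed(seed)
    cap = 1024
    times = np.empty(cap)
    states = np.empty(cap, np.int64)
    n = 0
    t = 0.0
    m = m0
    absorbed = False
    t_abs = np.nan
    while True:
        if absorbing and m == 0:
            absorbed = True
            t_abs = t
            break
        total = fw[m] + rv[m]
        if total <= 0.0:
            break  # legally frozen until max_t
        u = np.random.random()
        while u <= 0.0:
            u = np.random.random()
        dt = -np.log(u) / total
        if t + dt > max_t:
            break
        t += dt
        if np.random.random() * total < fw[m]:
            m += 1
        else:
            m -= 1
        if n == cap:
            cap *= 2
            nt = np.empty(cap)
            ns = np.empty(cap, np.int64)
            nt[:n] = times[:n]
            ns[:n] = states[:n]
            times = nt
            states = ns
        times[n] = t
        states[n] = m
        n += 1
    return times[:n].copy(), states[:n].copy(), absorbed, t_abs


@njit(cache=True)
def _residency_kernel(fw, rv, m0, max_t, seed, absorbing, out):
    """Accumulate per-state residency over [0, max_t]; returns (absorbed, t_abs)."""
    np.random.seed(seed)
    t = 0.0
    m = m0
    while t < max_t:
        if absorbing and m == 0:
            out[0] += max_t - t
            return True, t
        total = fw[m] + rv[m]
        if total <= 0.0:
            out[m] += max_t - t
            return False, np.nan
        u = np.random.random()
        while u <= 0.0:
            u = np.random.random()
        dt = -np.log(u) / total
        if t + dt >= max_t:
            out[m] += max_t - t
            return False, np.nan
        out[m] += dt
        t += dt
        if np.random.random() * total < fw[m]:
            m += 1
        else:
            m -= 1
    return False, np.nan


@njit(cache=True)
def _residency_ensemble_kernel(fw, rv, m0, max_t, seeds, absorbing, out, absorbed):
    for i in range(len(seeds)):
        a, _ = _residency_kernel(fw, rv, m0, max_t, seeds[i], absorbing, out[i])
        absorbed[i] = a


@njit(cache=True)
def _first_passage_kernel(fw, rv, m0, m_star, max_t, seed, absorbing):
    """First time m < m_star; returns (t, censored)."""
    np.random.seed(seed)
    t = 0.0
    m = m0
    while True:
        if m < m_star:
            return t, False
        if absorbing and m == 0:
            return max_t, True  # only reachable when m_star == 0: frozen at 0
        total = fw[m] + rv[m]
        if total <= 0.0:
            return max_t, True
        u = np.random.random()
        while u <= 0.0:
            u = np.random.random()
        dt = -np.log(u) / total
        t += dt
        if t > max_t:
            return max_t, True
        if np.random.random() * total < fw[m]:
            m += 1
        else:
            m -= 1


@njit(cache=True)
def _first_passage_ensemble_kernel(fw, rv, m0, m_star, max_t, seeds, absorbing, times, censored):
    for i in range(len(seeds)):
        t, c = _first_passage_kernel(fw, rv, m0, m_star, max_t, seeds[i], absorbing)
        times[i] = t
        censored[i] = c


@njit(cache=True)
def _falloff_kernel(fw, rv, m0, stop_m, max_t, seed):
    """Absorbing walk from m0; returns 0 if absorbed at 0 before reaching
    stop_m, 1 if stop_m reached first, 2 if censored at max_t."""
    np.random.seed(seed)
    t = 0.0
    m = m0
    while True:
        if m == 0:
            return 0
        if m >= stop_m:
            return 1
        total = fw[m] + rv[m]
        if total <= 0.0:
            return 2
        u = np.random.random()
        while u <= 0.0:
            u = np.random.random()
        dt = -np.log(u) / total
        t += dt
        if t > max_t:
            return 2
        if np.random.random() * total < fw[m]:
            m += 1
        else:
            m -= 1


@njit(cache=True)
def _falloff_ensemble_kernel(fw, rv, m0, stop_m, max_t, seeds, outcomes):
    for i in range(len(seeds)):
        outcomes[i] = _falloff_kernel(fw, rv, m0, stop_m, max_t, seeds[i])


# ---------------------------------------------------------------------------
# public simulation API
# ---------------------------------------------------------------------------


def derive_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic per-replicate 31-bit seeds from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return (ss.generate_state(n, dtype=np.uint32) >> 1).astype(np.int64)


def gillespie_run(
    rates: RateTable,
    m0: int,
    max_t: float,
    boundary: str = ABSORBING,
    seed: int = 0,
) -> Trajectory:
    """Exact stochastic simulation of one R-loop trajectory.

    Waiting times at state m are exponential with rate v_f(m)+v_r(m)
    (boundary-adjusted); the next state is chosen with probability
    proportional to its rate.  The run is censored at ``max_t`` or stops at
    absorption (m = 0 in absorbing mode).  Identical inputs give identical
    trajectories.
    """
    n = rates.n_positions
    if not 0 <= m0 <= n:
        raise ValueError(f"m0 must be in 0..{n}, got {m0}")
    if max_t <= 0:
        raise ValueError("max_t must be positive")
    absorbing = _check_boundary(boundary)
    fw, rv = rates.full_arrays()
    times, states, absorbed, t_abs = _traj_kernel(
        fw, rv, int(m0), float(max_t), int(seed), absorbing
    )
    return Trajectory(
        times=np.concatenate([[0.0], times]),
        states=states,
        m0=int(m0),
        max_t=float(max_t),
        n_positions=n,
        absorbed=bool(absorbed),
        absorption_time=float(t_abs),
        seed=int(seed),
    )


def simulate_ensemble(
    rates: RateTable,
    m0: int,
    max_t: float,
    reps: int,
    seed: int,
    boundary: str = ABSORBING,
) -> list[Trajectory]:
    """``reps`` independent trajectories with per-replicate derived seeds."""
    return [
        gillespie_run(rates, m0, max_t, boundary, int(s))
        for s in derive_seeds(seed, reps)
    ]


@dataclass(frozen=True)
class ResidencyEnsemble:
    """Per-state residency times for a replicate ensemble (reps x (N+1)).

    Row i holds the time replicate i spent in each state over [0, max_t];
    rows sum to max_t exactly (post-absorption time is booked at m = 0).
    """

    residency: np.ndarray
    max_t: float
    m0: int
    absorbed: np.ndarray = field(repr=False, default=None)

    @property
    def reps(self) -> int:
        return self.residency.shape[0]

    @property
    def n_positions(self) -> int:
        return self.residency.shape[1] - 1


def simulate_residency(
    rates: RateTable,
    m0: int,
    max_t: float,
    reps: int,
    seed: int,
    boundary: str = ABSORBING,
) -> ResidencyEnsemble:
    """Ensemble of per-state residency times (no event paths stored).

    This is the memory-light workhorse behind occupancy and threshold
    statistics for large replicate counts.
    """
    n = rates.n_positions
    if not 0 <= m0 <= n:
        raise ValueError(f"m0 must be in 0..{n}, got {m0}")
    if max_t <= 0 or reps < 1:
        raise ValueError("max_t must be positive and reps >= 1")
    absorbing = _check_boundary(boundary)
    fw, rv = rates.full_arrays()
    out = np.zeros((reps, n + 1))
    absorbed = np.zeros(reps, dtype=np.bool_)
    seeds = derive_seeds(seed, reps)
    _residency_ensemble_kernel(
        fw, rv, int(m0), float(max_t), seeds, absorbing, out, absorbed
    )
    return ResidencyEnsemble(residency=out, max_t=float(max_t), m0=int(m0), absorbed=absorbed)
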