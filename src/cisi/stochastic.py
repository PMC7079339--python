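"""Discrete-event stochastic simulation of the tumor-immune models.

The deterministic net rates are decomposed into elementary birth/death
events with mass-action propensities and simulated with adaptive
tau-leaping: reactions that could drive a low-copy species negative are
classified *critical* and fired one at a time (exact SSA timing), all
others are leaped with Poisson firing numbers under a bounded relative
propensity change per leap.  When even the leap candidate step is of the
order of single-reaction waiting times the engine falls back to exact SSA
steps.  Tumor extinction (T = 0) is exactly absorbing because states are
integer counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .models import BaseParams

__all__ = [
    "Reaction",
    "ReactionSystem",
    "Trajectory",
    "MeanTrajectory",
    "build_base_reactions",
    "simulate",
    "mean_trajectory",
]

DEFAULT_EPSILON = 0.03  # tau-leap relative propensity-change bound (convention)
N_CRITICAL = 10  # copy-number threshold below which consuming reactions fire exactly
SSA_FACTOR = 10.0  # leap < SSA_FACTOR expected reaction times -> exact stepping
SSA_BATCH = 100


class PropensityError(RuntimeError):
    """Raised when a propensity evaluates to a non-finite or negative value."""


@dataclass(frozen=True)
class Reaction:
    """One elementary event: an integer state change and its propensity."""

    name: str
    change: tuple
    propensity: Callable[[np.ndarray, float], float]


@dataclass
class ReactionSystem:
    """A set of species and reactions, with optional time-dependent rates.

    ``propensities(x, t)`` evaluates all reaction propensities at integer
    state ``x`` and time ``t``.  ``rate_breakpoints`` lists times at which a
    time-dependent rate jumps (leaps never cross them).
    """

    species: tuple
    reactions: list
    propensities: Optional[Callable[[np.ndarray, float], np.ndarray]] = None
    rate_breakpoints: tuple = ()

    def __post_init__(self) -> None:
        for r in self.reactions:
            if len(r.change) != len(self.species):
                raise ValueError(
                    f"reaction {r.name!r} change vector has wrong dimension"
                )
        if self.propensities is None:
            rs = list(self.reactions)

            def _props(x, t, _rs=rs):
                return np.array([r.propensity(x, t) for r in _rs])

            self.propensities = _props

    @property
    def change_matrix(self) -> np.ndarray:
        return np.array([r.change for r in self.reactions], dtype=np.int64)


@dataclass
class Trajectory:
    """Recorded integer-count time series of one seeded stochastic run."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, n_species), integer counts
    species: tuple
    seed: int
    params: dict = field(default_factory=dict)
    schedule: dict = field(default_factory=dict)

    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def first_passage_time(self, species: str, level: float) -> Optional[float]:
        """First recorded time at which ``species`` count >= ``level``."""
        j = self.species.index(species)
        hit = np.flatnonzero(self.states[:, j] >= level)
        return float(self.times[hit[0]]) if hit.size else None


@dataclass
class MeanTrajectory:
    """Per-time mean and standard deviation over independent replicates."""

    times: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    species: tuple
    n_reps: int
    seeds: tuple


def build_base_reactions(
    params: BaseParams, k_of_t: Optional[Callable[[float], float]] = None,
    rate_breakpoints: Sequence[float] = (),
) -> ReactionSystem:
    """Six-reaction decomposition of the base model.

    tumor birth (a T), tumor crowding death (a b T^2), killing
    (k(t) T E), effector supply (sigma), effector death (d E), and effector
    modulation (|m| T E, E -> E-1 for m < 0, E -> E+1 for m > 0).  The
    summed drift (propensity times change vector) equals the deterministic
    RHS at every state.
    """
    p = params
    if k_of_t is None:
        k_fun = lambda t: p.k  # noqa: E731
    else:
        k_fun = k_of_t
    m_change = 1 if p.m > 0 else -1
    abs_m = abs(p.m)

    reactions = [
        Reaction("tumor_birth", (1, 0), lambda x, t: p.a * x[0]),
        Reaction("tumor_crowding", (-1, 0), lambda x, t: p.a * p.b * x[0] * x[0]),
        Reaction("killing", (-1, 0), lambda x, t: k_fun(t) * x[0] * x[1]),
        Reaction("effector_supply", (0, 1), lambda x, t: p.sigma),
        Reaction("effector_death", (0, -1), lambda x, t: p.d * x[1]),
        Reaction("effector_modulation", (0, m_change), lambda x, t: abs_m * x[0] * x[1]),
    ]

    def propensities(x, t):
        T = float(x[0])
        E = float(x[1])
        return np.array(
            [
                p.a * T,
                p.a * p.b * T * T,
                k_fun(t) * T * E,
                p.sigma,
                p.d * E,
                abs_m * T * E,
            ]
        )

    return ReactionSystem(
        species=("T", "E"),
        reactions=reactions,
        propensities=propensities,
        rate_breakpoints=tuple(sorted(set(float(b) for b in rate_breakpoints))),
    )


def _tau_candidate(
    x: np.ndarray, mu: np.ndarray, sig2: np.ndarray, epsilon: float, g: float = 3.0
) -> float:
    """Species-bound leap size limiting relative propensity change to ~epsilon."""
    tau = math.inf
    for i in range(x.size):
        bound = max(epsilon * x[i] / g, 1.0)
        if mu[i] != 0.0:
            tau = min(tau, bound / abs(mu[i]))
        if sig2[i] > 0.0:
            tau = min(tau, bound * bound / sig2[i])
    return tau


def simulate(
    system: ReactionSystem,
    init,
    t_max: float,
    seed: int,
    record_dt: float = 1.0,
    *,
    epsilon: float = DEFAULT_EPSILON,
    boluses: Sequence[tuple] = (),
    t0: float = 0.0,
    n_critical: int = N_CRITICAL,
    params_snapshot: Optional[dict] = None,
    schedule_snapshot: Optional[dict] = None,
) -> Trajectory:
    """Run one seeded adaptive tau-leaping trajectory to ``t_max``.

    ``boluses`` is a sequence of ``(time, species_index, amount)`` events
    adding ``amount`` cells instantaneously.  States are recorded at
    ``t0 + i * record_dt``, at every bolus instant (post-addition), and at
    ``t_max``.  Counts never go negative: leaps that would overshoot are
    halved and redrawn.  Identical inputs reproduce the trajectory
    bit-identically.
    """
    if t_max <= t0:
        raise ValueError("t_max must exceed t0")
    if record_dt <= 0:
        raise ValueError("record_dt must be positive")
    x = np.asarray(init, dtype=np.int64)
    if x.shape != (len(system.species),) or np.any(x < 0):
        raise ValueError("init must be non-negative integers matching species")

    rng = np.random.default_rng(seed)
    V = system.change_matrix  # (R, S)
    V2 = V * V
    props = system.propensities
    consumes = [np.flatnonzero(V[j] < 0) for j in range(V.shape[0])]

    bolus_map: dict[float, list[tuple[int, int]]] = {}
    for bt, si, amount in boluses:
        bolus_map.setdefault(float(bt), []).append((int(si), int(amount)))

    rec_times = list(np.arange(t0, t_max, record_dt)) + [t_max]
    event_times = sorted(
        set(rec_times)
        | set(bolus_map)
        | {b for b in system.rate_breakpoints if t0 < b < t_max}
    )
    event_times = [e for e in event_times if t0 <= e <= t_max]

    times_out = [t0]
    states_out = [x.copy()]
    t = t0

    for t_event in event_times:
        while t < t_event:
            a = props(x, t)
            if not np.all(np.isfinite(a)) or np.any(a < 0):
                raise PropensityError(f"bad propensities {a} at t={t}, x={x}")
            a0 = float(a.sum())
            if a0 == 0.0:
                t = t_event
                break
            # critical = active reactions that consume a low-copy species
            crit = np.zeros(a.size, dtype=bool)
            for j in range(a.size):
                if a[j] > 0 and consumes[j].size and np.any(
                    x[consumes[j]] < n_critical
                ):
                    crit[j] = True
            a_nc = np.where(crit, 0.0, a)
            mu = V.T @ a_nc
            sig2 = V2.T @ a_nc
            tau1 = _tau_candidate(x, mu, sig2, epsilon)

            if tau1 < SSA_FACTOR / a0:
                # exact SSA steps for a short batch
                cum = np.cumsum(a)
                for _ in range(SSA_BATCH):
                    dt = rng.exponential(1.0 / a0)
                    if t + dt > t_event:
                        t = t_event
                        break
                    t += dt
                    j = int(np.searchsorted(cum, rng.random() * a0))
                    x = x + V[j]
                    a = props(x, t)
                    a0 = float(a.sum())
                    if a0 == 0.0:
                        t = t_event
                        break
                    cum = np.cumsum(a)
                continue

            ac0 = float(a[crit].sum())
            tau2 = rng.exponential(1.0 / ac0) if ac0 > 0 else math.inf
            for _attempt in range(60):
                fire_critical = tau2 < tau1 and t + tau2 <= t_event
                tau = min(tau1, tau2, t_event - t)
                # midpoint propensity evaluation removes the O(tau) mean bias
                # of the plain explicit leap
                x_mid = np.maximum(x + 0.5 * tau * mu, 0.0)
                a_mid = props(x_mid, t)
                a_mid = np.where(crit | ~np.isfinite(a_mid) | (a_mid < 0), a_nc, a_mid)
                kdraw = rng.poisson(a_mid * tau)
                dx = kdraw @ V
                if fire_critical:
                    cum_c = np.cumsum(np.where(crit, a, 0.0))
                    jc = int(np.searchsorted(cum_c, rng.random() * ac0))
                    dx = dx + V[jc]
                x_new = x + dx
                if np.all(x_new >= 0):
                    x = x_new
                    t = t + tau
                    break
                tau1 *= 0.5
                tau2 = rng.exponential(1.0 / ac0) if ac0 > 0 else math.inf
            else:
                raise RuntimeError("leap shrinking failed to avoid negative counts")

        # at the event time: apply boluses, then record
        if t_event in bolus_map:
            x = x.copy()
            for si, amount in bolus_map[t_event]:
                x[si] += amount
        times_out.append(t_event)
        states_out.append(x.copy())

    # all event times (record grid, rate breakpoints, bolus instants) are
    # recorded; drop exact duplicates
    times_arr = np.array(times_out)
    states_arr = np.array(states_out, dtype=np.int64)
    keep = np.ones(times_arr.size, dtype=bool)
    keep[1:] = np.diff(times_arr) > 0
    return Trajectory(
        times=times_arr[keep],
        states=states_arr[keep],
        species=system.species,
        seed=int(seed),
        params=params_snapshot or {},
        schedule=schedule_snapshot or {},
    )


def mean_trajectory(
    system: ReactionSystem,
    init,
    t_max: float,
    n_reps: int,
    base_seed: int,
    record_dt: float = 1.0,
    *,
    epsilon: float = DEFAULT_EPSILON,
    boluses: Sequence[tuple] = (),
) -> MeanTrajectory:
    """Mean and standard deviation over ``n_reps`` independently seeded runs.

    Replicates use seeds ``base_seed .. base_seed + n_reps - 1`` (distinct
    by construction).
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    seeds = tuple(int(base_seed) + i for i in range(n_reps))
    if len(set(seeds)) != n_reps:
        raise ValueError("replicate seeds collide")
    runs = [
        simulate(
            system,
            init,
            t_max,
            seed,
            record_dt,
            epsilon=epsilon,
            boluses=boluses,
        )
        for seed in seeds
    ]
    times = runs[0].times
    for r in runs[1:]:
        if not np.array_equal(r.times, times):
            raise RuntimeError("replicate recording grids differ")
    stack = np.stack([r.states for r in runs]).astype(float)
    return MeanTrajectory(
        times=times,
        mean=stack.mean(axis=0),
        sd=stack.std(axis=0, ddof=1),
        species=system.species,
        n_reps=n_reps,
        seeds=seeds,
    )
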