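"""Treatment schedules and combination-immunotherapy experiments.

Two interventions are modeled.  *Antibody therapy* permanently raises the
killing efficacy: starting at day ``tau_k`` the efficacy is increased by
``delta_k / delta_tau_k`` per treatment day until it reaches
``k0 + delta_k``, where it stays.  *Adoptive transfer* injects a total of
``delta_E`` effector cells in equal daily boluses over ``delta_tau_E``
days starting at day ``tau_E``; transferred cells are subject to the same
death/exhaustion dynamics as native effectors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass

import numpy as np

from .models import BaseParams
from .stochastic import (
    DEFAULT_EPSILON,
    Trajectory,
    build_base_reactions,
    simulate,
)

__all__ = [
    "TreatmentSchedule",
    "GridResult",
    "k_of_t",
    "k_breakpoints",
    "transfer_events",
    "run_treatment",
    "combination_grid",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TreatmentSchedule:
    """Timing and dosing of the two combined interventions.

    ``delta_k`` is the total (permanent) killing-efficacy increase delivered
    in daily steps over ``delta_tau_k`` days from ``tau_k``; ``delta_E`` is
    the total number of transferred effector cells delivered in daily
    boluses over ``delta_tau_E`` days from ``tau_E``.
    """

    tau_k: float = 50.0
    delta_tau_k: int = 1
    delta_k: float = 0.0
    tau_E: float = 50.0
    delta_tau_E: int = 1
    delta_E: float = 0.0

    def __post_init__(self) -> None:
        if self.delta_k < 0 or self.delta_E < 0:
            raise ValueError("doses must be non-negative")
        if self.delta_k > 0 and self.delta_tau_k < 1:
            raise ValueError("delta_tau_k must be >= 1 day when delta_k > 0")
        if self.delta_E > 0 and self.delta_tau_E < 1:
            raise ValueError("delta_tau_E must be >= 1 day when delta_E > 0")

    @property
    def start(self) -> float:
        starts = []
        if self.delta_k > 0:
            starts.append(self.tau_k)
        if self.delta_E > 0:
            starts.append(self.tau_E)
        return min(starts) if starts else math.inf


def k_of_t(schedule: TreatmentSchedule, k0: float):
    """Piecewise-constant killing efficacy under the daily-increment ramp.

    Each treatment day administers ``delta_k / delta_tau_k``; the increment
    takes effect at the end of that day, so ``k`` equals ``k0`` for
    ``t < tau_k + 1`` and ``k0 + delta_k`` permanently from
    ``t >= tau_k + delta_tau_k``.  The daily steps sum to ``delta_k``
    exactly (the last step absorbs rounding drift).
    """
    if k0 < 0:
        raise ValueError("k0 must be >= 0")
    s = schedule
    if s.delta_k == 0.0:
        return lambda t: k0
    step = s.delta_k / s.delta_tau_k

    def k_fun(t: float) -> float:
        n = math.floor(t - s.tau_k)
        if n <= 0:
            return k0
        if n >= s.delta_tau_k:
            return k0 + s.delta_k
        return k0 + n * step

    return k_fun


def k_breakpoints(schedule: TreatmentSchedule) -> tuple:
    """Times at which the killing efficacy jumps (leaps must not cross them)."""
    s = schedule
    if s.delta_k == 0.0:
        return ()
    return tuple(s.tau_k + i for i in range(1, s.delta_tau_k + 1))


def transfer_events(schedule: TreatmentSchedule) -> list[tuple[float, int]]:
    """Daily adoptive-transfer boluses as (day, integer cells) pairs.

    Boluses fall on days ``tau_E, tau_E + 1, ..., tau_E + delta_tau_E - 1``,
    each of ``round(delta_E / delta_tau_E)`` cells with the last bolus
    adjusted so the total equals ``delta_E`` exactly.
    """
    s = schedule
    if s.delta_E == 0.0:
        return []
    total = int(round(s.delta_E))
    n = s.delta_tau_E
    base = int(round(total / n))
    events = [(s.tau_E + i, base) for i in range(n - 1)]
    last = total - base * (n - 1)
    if last < 0:
        raise ValueError("rounding produced a negative final bolus; use fewer days")
    events.append((s.tau_E + n - 1, last))
    return events


def run_treatment(
    params: BaseParams,
    init,
    schedule: TreatmentSchedule,
    t_max: float,
    seed: int,
    *,
    record_dt: float = 1.0,
    epsilon: float = DEFAULT_EPSILON,
) -> Trajectory:
    """Stochastic base-model run with the treatment schedule applied.

    The killing-efficacy ramp is wired into the killing propensity and the
    transfer boluses are added to the effector count at their event
    instants.  A null schedule reproduces the untreated run bit-identically
    for the same seed.
    """
    k_fun = k_of_t(schedule, params.k)
    system = build_base_reactions(
        params, k_of_t=k_fun, rate_breakpoints=k_breakpoints(schedule)
    )
    boluses = [(day, 1, cells) for day, cells in transfer_events(schedule) if cells > 0]
    return simulate(
        system,
        init,
        t_max,
        seed,
        record_dt,
        epsilon=epsilon,
        boluses=boluses,
        params_snapshot={"model": "base", **{f: getattr(params, f) for f in ("a", "b", "k", "sigma", "d", "m")}},
        schedule_snapshot=asdict(schedule),
    )


@dataclass
class GridResult:
    """Outcome matrix of the combination dose-grid experiment.

    ``final_T[i, j, r]`` is the tumor count at the evaluation day for
    ``delta_k_values[i]``, ``delta_E_values[j]``, replicate ``r``;
    ``median_T`` is the per-cell median over replicates.  ``failed`` flags
    cells whose simulations raised (their entries are -1).
    """

    delta_k_values: np.ndarray
    delta_E_values: np.ndarray
    final_T: np.ndarray
    median_T: np.ndarray
    eval_day: float
    seeds: np.ndarray
    failed: np.ndarray

    def cleared(self, threshold: int = 0) -> np.ndarray:
        """Boolean matrix: median outcome at or below ``threshold`` cells."""
        return self.median_T <= threshold

    def clearance_frontier(self, threshold: int = 0) -> np.ndarray:
        """Minimal clearing delta_E per delta_k (NaN where none clears)."""
        cleared = self.cleared(threshold)
        out = np.full(len(self.delta_k_values), np.nan)
        for i in range(len(self.delta_k_values)):
            js = np.flatnonzero(cleared[i])
            if js.size:
                out[i] = self.delta_E_values[js[0]]
        return out


def combination_grid(
    params: BaseParams,
    init,
    delta_k_values,
    delta_E_values,
    *,
    schedule_template: TreatmentSchedule | None = None,
    eval_day: float = 120.0,
    n_reps: int = 5,
    base_seed: int = 1,
    record_dt: float = 1.0,
    epsilon: float = DEFAULT_EPSILON,
) -> GridResult:
    """Tumor outcome at ``eval_day`` over a (delta_k, delta_E) dose grid.

    The default template mirrors the single-day combination protocol:
    both interventions start at day 50 and last one day; outcomes are
    evaluated at day 120.  Each cell runs ``n_reps`` replicates with seeds
    ``base_seed + r``; per-cell failures are logged and flagged without
    aborting the grid.
    """
    dk = np.asarray(delta_k_values, dtype=float)
    dE = np.asarray(delta_E_values, dtype=float)
    if dk.size == 0 or dE.size == 0:
        raise ValueError("dose axes must be non-empty")
    tmpl = schedule_template or TreatmentSchedule(
        tau_k=50.0, delta_tau_k=1, tau_E=50.0, delta_tau_E=1
    )
    if eval_day <= min(tmpl.tau_k, tmpl.tau_E):
        raise ValueError("eval_day must be after treatment start")
    final = np.full((dk.size, dE.size, n_reps), -1, dtype=np.int64)
    failed = np.zeros((dk.size, dE.size), dtype=bool)
    seeds = np.array([int(base_seed) + r for r in range(n_reps)])
    for i, dki in enumerate(dk):
        for j, dEj in enumerate(dE):
            sched = TreatmentSchedule(
                tau_k=tmpl.tau_k,
                delta_tau_k=tmpl.delta_tau_k,
                delta_k=float(dki),
                tau_E=tmpl.tau_E,
                delta_tau_E=tmpl.delta_tau_E,
                delta_E=float(dEj),
            )
            for r, seed in enumerate(seeds):
                try:
                    traj = run_treatment(
                        params,
                        init,
                        sched,
                        eval_day,
                        int(seed),
                        record_dt=record_dt,
                        epsilon=epsilon,
                    )
                    final[i, j, r] = traj.states[-1, 0]
                except Exception:  # pragma: no cover - defensive
                    log.exception(
                        "grid cell (delta_k=%g, delta_E=%g, seed=%d) failed",
                        dki,
                        dEj,
                        seed,
                    )
                    failed[i, j] = True
        log.info("grid row %d/%d (delta_k=%g) done", i + 1, dk.size, dki)
    median = np.median(np.where(final < 0, np.nan, final), axis=2)
    return GridResult(
        delta_k_values=dk,
        delta_E_values=dE,
        final_T=final,
        median_T=median,
        eval_day=float(eval_day),
        seeds=seeds,
        failed=failed,
    )
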