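"""The standard in-silico protocols: induction at fixed exogenous
autoinducer, hysteresis scans, serial-dilution (decreasing concentration)
trajectories and first-passage-time campaigns.

Every protocol exists for both engines: the deterministic population-average
ODE model ("ode") and the multicell Gillespie simulation ("ssa").  All
normalized GFP values are relative to the deterministic full-induction
steady state (cA* = 100 nM) of the same construct.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ode, ssa
from .analysis import FptSample, ResponseDistribution
from .parameters import ParameterSet, build_parameter_set

DILUTION_FACTOR = 0.75      # hourly reduction of cA* in the serial protocol


@dataclass
class Protocol:
    """Settings of one induction/scan campaign."""

    construct: str = "lux01"
    grid: tuple = (0.0, 5.0, 10.0, 20.0, 40.0, 80.0)   # nM
    hours: float = 10.0
    realizations: int = 10
    bR: float = 20.0
    bI: float = 20.0
    N: int = 100
    seed: int = 0
    sample_every: float = 10.0   # min, SSA output grid

    def __post_init__(self):
        if self.realizations < 1:
            raise ValueError("realizations must be at least 1")
        g = np.asarray(self.grid, dtype=float)
        if g.size == 0:
            raise ValueError("concentration grid must be non-empty")
        if g.size > 1 and np.any(np.diff(g) <= 0):
            raise ValueError("concentration grid must be strictly increasing")

    def params(self) -> ParameterSet:
        return build_parameter_set(
            {"bR": self.bR, "bI": self.bI, "N": self.N}, self.construct)


def _rep_rng(seed: int, *stream) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *stream])


# ---------------------------------------------------------------------------
# induction at fixed cA*
# ---------------------------------------------------------------------------

def induction_experiment(protocol: Protocol, engine: str = "ssa"
                         ) -> list[ResponseDistribution]:
    """Snapshot of per-cell normalized GFP after ``protocol.hours`` of
    induction, at every concentration of the grid.

    SSA snapshots pool all cells of all realizations; the ODE engine yields
    a single population-average value per concentration.
    """
    params = protocol.params()
    gmax = ode.gfp_max(params)
    basal = ode.basal_state(params)
    out = []
    for j, ca in enumerate(protocol.grid):
        if protocol.hours == 0:
            if engine == "ode":
                vals = np.array([basal[ode.GFP_INDEX] / gmax])
            else:
                rng = _rep_rng(protocol.seed, j, 0)
                pop = ssa.population_from_concentrations(basal, params.replace(
                    cA_star=float(ca)), rng)
                vals = pop.gfp_nM(params) / gmax
        elif engine == "ode":
            state, _ = ode.steady_state_from(basal, float(ca), params,
                                             protocol.hours)
            vals = np.array([state[ode.GFP_INDEX] / gmax])
        elif engine == "ssa":
            p = params.replace(cA_star=float(ca))
            pooled = []
            for rep in range(protocol.realizations):
                rng = _rep_rng(protocol.seed, j, rep)
                pop = ssa.population_from_concentrations(basal, p, rng)
                res = ssa.advance(pop, protocol.hours * 60.0, p, rng,
                                  sample_every=protocol.hours * 60.0)
                pooled.append(res.pop.gfp_nM(p) / gmax)
            vals = np.concatenate(pooled)
        else:
            raise ValueError(f"unknown engine {engine!r}")
        out.append(ResponseDistribution(float(ca), vals))
    return out


def run_induction(params: ParameterSet, cA_star: float, hours: float,
                  n_reps: int, seed: int,
                  sample_every: float = 10.0) -> list[ssa.Trajectory]:
    """SSA induction trajectories (one per realization) at fixed cA*."""
    p = params.replace(cA_star=float(cA_star))
    basal = ode.basal_state(params)
    trajs = []
    for rep in range(n_reps):
        rng = _rep_rng(seed, 7, rep)
        pop = ssa.population_from_concentrations(basal, p, rng)
        res = ssa.advance(pop, hours * 60.0, p, rng,
                          sample_every=sample_every)
        trajs.append(res.trajectory)
    return trajs


# ---------------------------------------------------------------------------
# hysteresis
# ---------------------------------------------------------------------------

def hysteresis_scan(protocol: Protocol, direction: str = "increasing",
                    engine: str = "ode") -> pd.DataFrame:
    """Continuation scan over the concentration grid.

    The terminal state at each grid point seeds the next point in scan
    order (low start for increasing, fully induced start for decreasing).
    Returns a tidy table (construct, branch, cA_star_nM, induction_time_h,
    gfp_norm).
    """
    if direction not in ("increasing", "decreasing"):
        raise ValueError("direction must be 'increasing' or 'decreasing'")
    params = protocol.params()
    gmax = ode.gfp_max(params)
    grid = list(protocol.grid)
    order = grid if direction == "increasing" else grid[::-1]
    rows = []
    if engine == "ode":
        state = (ode.basal_state(params) if direction == "increasing"
                 else ode.induced_state(params))
        for ca in order:
            state, _ = ode.steady_state_from(state, float(ca), params,
                                             protocol.hours)
            rows.append((protocol.construct, direction, float(ca),
                         protocol.hours, state[ode.GFP_INDEX] / gmax))
    elif engine == "ssa":
        rng = _rep_rng(protocol.seed, 11)
        start = (ode.basal_state(params) if direction == "increasing"
                 else ode.induced_state(params))
        pop = ssa.population_from_concentrations(
            start, params.replace(cA_star=float(order[0])), rng)
        for ca in order:
            p = params.replace(cA_star=float(ca))
            res = ssa.advance(pop, pop.t_min + protocol.hours * 60.0, p, rng,
                              sample_every=protocol.hours * 60.0)
            pop = res.pop
            rows.append((protocol.construct, direction, float(ca),
                         protocol.hours, float(np.mean(pop.gfp_nM(p))) / gmax))
    else:
        raise ValueError(f"unknown engine {engine!r}")
    return pd.DataFrame(rows, columns=["construct", "branch", "cA_star_nM",
                                       "induction_time_h", "gfp_norm"])


def deterministic_bistable_bounds(params: ParameterSet,
                                  ca_max: float = 30.0,
                                  step: float = 0.5,
                                  refine: float = 0.05,
                                  hours: float = 100.0,
                                  distinct: float = 0.1
                                  ) -> tuple[float, float] | None:
    """Boundaries of the deterministic bistable region.

    Scans cA* from 0 to ``ca_max``, integrating ``hours`` from both the
    non-induced and the fully induced state; a point is bistable when the
    two branches settle more than ``distinct``×GFP_max apart.  The outermost
    bistable points are refined by bisection to ``refine`` nM.  Returns
    (lower, upper) in nM, or None when no bistability is found.
    """
    low0 = ode.basal_state(params)
    high0 = ode.induced_state(params)
    gmax = high0[ode.GFP_INDEX]

    def bistable(ca: float) -> bool:
        gl, _ = ode.steady_state_from(low0, ca, params, hours)
        gh, _ = ode.steady_state_from(high0, ca, params, hours)
        return (gh[ode.GFP_INDEX] - gl[ode.GFP_INDEX]) / gmax > distinct

    grid = np.arange(0.0, ca_max + step / 2, step)
    flags = np.array([bistable(float(ca)) for ca in grid])
    idx = np.nonzero(flags)[0]
    if idx.size == 0:
        return None

    def bisect(a: float, b: float, want_upper: bool) -> float:
        # invariant: one endpoint bistable, the other not
        while b - a > refine:
            m = 0.5 * (a + b)
            if bistable(m) == want_upper:
                a = m
            else:
                b = m
        return a if want_upper else b

    lo = grid[idx[0]]
    if idx[0] > 0:
        lo = bisect(float(grid[idx[0] - 1]), float(lo), want_upper=False)
    hi = float(grid[idx[-1]])
    if idx[-1] + 1 < len(grid):
        hi = bisect(hi, float(grid[idx[-1] + 1]), want_upper=True)
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# serial dilution (decreasing concentration)
# ---------------------------------------------------------------------------

def dilution_schedule(c0: float, hold_hours: float,
                      total_hours: float) -> list[tuple[float, float]]:
    """Piecewise-constant cA* schedule: hold ``c0`` for ``hold_hours``, then
    reduce by 25% at every subsequent hour."""
    sched = [(0.0, float(c0))]
    t, c = hold_hours, c0
    while t < total_hours:
        c *= DILUTION_FACTOR
        sched.append((t, float(c)))
        t += 1.0
    # a zero-hold protocol starts directly at the first reduced level
    if len(sched) > 1 and sched[1][0] == 0.0:
        sched.pop(0)
    return sched


def decreasing_concentration_experiment(initial_induction: dict,
                                        params: ParameterSet,
                                        engine: str = "ode",
                                        total_hours: float = 30.0,
                                        seed: int = 0,
                                        sample_every: float = 5.0):
    """Serial-dilution protocol: induce at ``initial_induction['cA_star']``
    for ``initial_induction['hours']``, then reduce cA* hourly by 25%.

    Returns ``(times_min, gfp_norm)`` for the ODE engine (population
    average), or an SSA :class:`~luxswitch.ssa.Trajectory` with the same
    schedule applied.
    """
    c0 = float(initial_induction["cA_star"])
    h0 = float(initial_induction["hours"])
    if h0 < 0:
        raise ValueError("initial induction hours must be non-negative")
    sched = dilution_schedule(c0, h0, total_hours)
    gmax = ode.gfp_max(params)
    basal = ode.basal_state(params)
    if engine == "ode":
        times, gfp = [0.0], [basal[ode.GFP_INDEX] / gmax]
        state = basal
        for k, (t_start, ca) in enumerate(sched):
            t_stop = (sched[k + 1][0] if k + 1 < len(sched) else total_hours)
            if t_stop <= t_start:
                continue
            p = params.replace(cA_star=ca)
            traj = ode.integrate(state, (t_stop - t_start) * 60.0, p)
            ts = np.arange(sample_every, (t_stop - t_start) * 60.0 + 1e-6,
                           sample_every)
            if ts.size:
                times.extend((t_start * 60.0 + ts).tolist())
                gfp.extend(np.atleast_1d(traj.gfp(ts) / gmax).tolist())
            state = traj.final_state
        return np.array(times), np.array(gfp)
    if engine == "ssa":
        rng = _rep_rng(seed, 13)
        pop = ssa.population_from_concentrations(
            basal, params.replace(cA_star=c0), rng)
        parts = []
        for k, (t_start, ca) in enumerate(sched):
            t_stop = (sched[k + 1][0] if k + 1 < len(sched) else total_hours)
            if t_stop <= t_start:
                continue
            p = params.replace(cA_star=ca)
            res = ssa.advance(pop, t_stop * 60.0, p, rng,
                              sample_every=sample_every)
            pop = res.pop
            parts.append(res.trajectory)
        return _concat_trajectories(parts)
    raise ValueError(f"unknown engine {engine!r}")


def _concat_trajectories(parts: list[ssa.Trajectory]) -> ssa.Trajectory:
    keep = [parts[0]] + [p for p in parts[1:]]
    return ssa.Trajectory(
        times=np.concatenate([p.times for p in keep]),
        ids=np.concatenate([p.ids for p in keep]),
        gfp_counts=np.concatenate([p.gfp_counts for p in keep]),
        volumes=np.concatenate([p.volumes for p in keep]),
        aext=np.concatenate([p.aext for p in keep]),
        species=None,
    )


# ---------------------------------------------------------------------------
# first passage times
# ---------------------------------------------------------------------------

def fpt_campaign(grid, direction: str, n_reps: int, params: ParameterSet,
                 seed: int = 0, horizon_hours: float = 100.0,
                 threshold: float = 0.5) -> list[FptSample]:
    """Single-cell first-passage-time draws at each concentration.

    The cell starts from the basal ("low_to_high") or the fully induced
    state ("high_to_low"); the external autoinducer is clamped at cA*, the
    cell grows and divides, and the followed lineage continues through one
    daughter chosen uniformly at random.  Runs that do not cross the
    half-maximum GFP threshold within the horizon are censored at the
    horizon.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    if direction not in ("low_to_high", "high_to_low"):
        raise ValueError("direction must be 'low_to_high' or 'high_to_low'")
    gmax = ode.gfp_max(params)
    thr = threshold * gmax
    if direction == "low_to_high":
        start = ode.basal_state(params)
        stop_dir = 1
    else:
        start = ode.induced_state(params)
        stop_dir = -1
    out = []
    for j, ca in enumerate(grid):
        draws = np.empty(n_reps)
        cens = np.zeros(n_reps, dtype=bool)
        for rep in range(n_reps):
            rng = _rep_rng(seed, 17, j, rep)
            fpt_min, censored = ssa.fpt_single_cell(
                params, float(ca), start, thr, horizon_hours * 60.0, rng,
                direction=stop_dir)
            draws[rep] = fpt_min / 60.0
            cens[rep] = censored
        out.append(FptSample(float(ca), draws, cens))
    return out
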