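"""Exact stochastic simulation of a population of growing, dividing cells.

Every chemical reaction in every cell, the membrane diffusion of the
autoinducer and the chemostat exchange of the medium are treated as one
global Gillespie system.  Cell *i* grows exponentially,
``V_i(t) = V0·2^(t/τ_i)`` with clock ``t`` reset at birth, and divides when
its clock reaches its individually sampled cycle duration τ_i.  At division
the DNA-bound activator complex is detached, all free molecules are
partitioned binomially between the daughters, each daughter receives one
promoter copy, and — under the constant-density dilution protocol — one cell
chosen uniformly at random among the N+1 present (newborn included) is
washed out so that the census stays at N.

The reaction loop runs in a compiled kernel (:mod:`luxswitch._kernel`);
divisions, partitioning and trajectory sampling happen here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import _kernel
from .parameters import (MOLECULES_PER_NM_UM3, ParameterSet,
                         concentration_to_count, sample_cell_cycle)
from .reactions import reaction_catalog

_F = MOLECULES_PER_NM_UM3

#: per-cell species order shared with the kernel
SPECIES = ("mRNA_luxR", "mRNA_luxIgfp", "luxR", "luxIgfp", "A",
           "C", "C2", "DNA_free", "DNA_bound")
I_GFP = 3


def pack_params(p: ParameterSet) -> np.ndarray:
    """Pack rate constants into the kernel's parameter vector."""
    return np.array([
        p.alphaR * p.kR, p.alphaI * p.kI, p.kR, p.kI, p.pR, p.pI, p.kA,
        (p.k1_minus / p.Kd1) / _F, p.k1_minus,
        (p.k2_minus / p.Kd2) / _F, p.k2_minus,
        (p.klux_minus / p.Kdlux) / _F, p.klux_minus,
        p.D, p.dA, p.dmR, p.dmI, p.dR, p.dI, p.dC, p.dC2,
        p.gamma, p.gamma * p.cA_star * _F * p.Vtot, p.Vtot, p.V0, _F,
        math.log(2.0) / p.tau,
    ])


# ---------------------------------------------------------------------------
# state containers
# ---------------------------------------------------------------------------

@dataclass
class CellState:
    """Snapshot of one cell."""

    counts: np.ndarray          # (9,) integer molecule counts
    volume: float               # μm³
    clock: float                # min since last division
    tau_i: float                # min, sampled cycle duration
    cell_id: int
    parent_id: int = -1

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(SPECIES),):
            raise ValueError("counts must have one entry per species")
        if np.any(self.counts < 0):
            raise ValueError("molecule counts must be non-negative")
        if self.counts[7] + self.counts[8] != 1:
            raise ValueError("each cell carries exactly one promoter copy")


@dataclass
class PopulationState:
    """N cells plus the shared medium."""

    x: np.ndarray               # (N, 9) int64 counts
    aext: float                 # external autoinducer molecule count
    t_min: float                # global time
    birth: np.ndarray           # (N,) absolute birth times, min
    taui: np.ndarray            # (N,) cycle durations, min
    ids: np.ndarray             # (N,) unique cell ids
    next_id: int

    @property
    def n_cells(self) -> int:
        return self.x.shape[0]

    def volumes(self, params: ParameterSet) -> np.ndarray:
        age = self.t_min - self.birth
        return params.V0 * 2.0 ** (age / self.taui)

    def cells(self, params: ParameterSet) -> list[CellState]:
        vols = self.volumes(params)
        return [CellState(self.x[i].copy(), float(vols[i]),
                          float(self.t_min - self.birth[i]),
                          float(self.taui[i]), int(self.ids[i]))
                for i in range(self.n_cells)]

    def gfp_nM(self, params: ParameterSet) -> np.ndarray:
        return self.x[:, I_GFP] / (_F * self.volumes(params))


class Event(NamedTuple):
    time: float
    kind: str                   # "reaction" | "division" | "removal"
    cell_id: int
    detail: tuple


@dataclass
class EventLog:
    """Time-ordered record of reactions (optional), divisions and removals."""

    events: list = field(default_factory=list)

    def append(self, ev: Event) -> None:
        if self.events and ev.time < self.events[-1].time - 1e-9:
            raise ValueError("event times must be non-decreasing")
        self.events.append(ev)

    def of_kind(self, kind: str) -> list[Event]:
        return [e for e in self.events if e.kind == kind]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.time, e.kind, e.cell_id, ",".join(map(str, e.detail)))
             for e in self.events],
            columns=["time_min", "event", "cell_id", "detail"])


@dataclass
class Trajectory:
    """Per-cell record on a fixed output grid."""

    times: np.ndarray           # (T,) min
    ids: np.ndarray             # (T, N)
    gfp_counts: np.ndarray      # (T, N)
    volumes: np.ndarray         # (T, N) μm³
    aext: np.ndarray            # (T,) molecule count
    species: np.ndarray | None  # (T, N, 9) when recorded

    def gfp_nM(self) -> np.ndarray:
        return self.gfp_counts / (_F * self.volumes)

    def gfp_norm(self, gfp_max_nM: float) -> np.ndarray:
        return self.gfp_nM() / gfp_max_nM

    def to_long_dataframe(self) -> pd.DataFrame:
        T, N = self.ids.shape
        return pd.DataFrame({
            "time_min": np.repeat(self.times, N),
            "cell_id": self.ids.ravel(),
            "gfp_count": self.gfp_counts.ravel(),
            "volume_um3": self.volumes.ravel(),
            "gfp_nM": self.gfp_nM().ravel(),
        })


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def population_from_concentrations(conc: np.ndarray, params: ParameterSet,
                                   rng: np.random.Generator) -> PopulationState:
    """Build a newborn population whose counts match the given ODE state.

    ``conc`` is the 10-component deterministic state (nM); per-cell counts
    are the rounded count equivalents in the birth volume V0, each cell
    receives one free promoter copy, and cycle durations are sampled
    independently.  The external pool matches the A_ext concentration in
    ``Vext``.
    """
    conc = np.asarray(conc, dtype=float)
    N = params.N
    x = np.zeros((N, len(SPECIES)), dtype=np.int64)
    for s in range(7):
        x[:, s] = concentration_to_count(max(conc[s], 0.0), params.V0)
    x[:, 7] = 1
    x[:, 8] = 0
    aext = float(concentration_to_count(max(conc[9], 0.0), params.Vext))
    taui = np.array([sample_cell_cycle(params.tau, params.lam, rng)
                     for _ in range(N)])
    return PopulationState(x=x, aext=aext, t_min=0.0,
                           birth=np.zeros(N), taui=taui,
                           ids=np.arange(N, dtype=np.int64), next_id=N)


# ---------------------------------------------------------------------------
# reference propensities (used by tests; the kernel maintains these
# incrementally)
# ---------------------------------------------------------------------------

def compute_propensities(pop: PopulationState, params: ParameterSet) -> pd.Series:
    """Propensity of every channel of every cell plus the external channels.

    Returns a Series indexed by (cell, channel-name); the external channels
    use cell = -1.  Second-order propensities scale as V0/V_i(t); the
    diffusion of external autoinducer into cell i has propensity
    ``D·r_i(t)·n_Aext`` with ``r_i = V_i/(Vtot − ΣV_j)``.
    """
    if np.any(pop.x < 0):
        raise ValueError("negative count detected")
    catalog = reaction_catalog(params)
    vols = pop.volumes(params)
    vct = vols.sum()
    rows = {}
    for i in range(pop.n_cells):
        counts = dict(zip(SPECIES, pop.x[i]))
        for ch in catalog:
            if ch.scope == "external":
                continue
            if ch.name == "diffusion_in":
                r_i = vols[i] / (params.Vtot - vct)
                a = ch.rate_constant * r_i * pop.aext
            elif ch.order == 2:
                sps = list(ch.reactants.items())
                if ch.symmetric:
                    n = counts[sps[0][0]]
                    a = ch.rate_constant / (_F * vols[i]) * n * (n - 1) / 2.0
                else:
                    a = ch.rate_constant / (_F * vols[i])
                    for sp, nu in sps:
                        a *= counts[sp]
            else:
                a = ch.rate_constant
                for sp, nu in ch.reactants.items():
                    a *= counts[sp] ** nu
            rows[(i, ch.name)] = a
    for ch in catalog:
        if ch.scope != "external":
            continue
        a = ch.rate_constant * (1.0 if ch.order == 0 else pop.aext)
        rows[(-1, ch.name)] = a
    return pd.Series(rows, name="propensity")


# ---------------------------------------------------------------------------
# division and dilution
# ---------------------------------------------------------------------------

def _partition_counts(counts: np.ndarray,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Binomially split free molecules; each daughter gets one promoter.

    The DNA-bound complex, if present, is detached into the free C2 pool
    before partitioning.
    """
    c = counts.copy()
    if c[8] == 1:               # detach bound complex prior to distribution
        c[8] = 0
        c[7] = 1
        c[6] += 1
    d1 = np.zeros_like(c)
    for s in range(7):
        d1[s] = rng.binomial(int(c[s]), 0.5)
    d2 = c.copy()
    d2[:7] -= d1[:7]
    d1[7] = d2[7] = 1
    d1[8] = d2[8] = 0
    return d1, d2


def divide_cell(cell: CellState, params: ParameterSet,
                rng: np.random.Generator) -> tuple[CellState, CellState]:
    """Split a mother cell at the end of its cycle into two newborns.

    Both daughters start with volume V0, clock 0 and independently sampled
    cycle durations; per-species counts over the daughters sum to the
    mother's (after detaching any promoter-bound complex).
    """
    if not math.isclose(cell.clock, cell.tau_i, rel_tol=1e-9, abs_tol=1e-6):
        raise ValueError("cells divide exactly when their clock reaches tau_i")
    c1, c2 = _partition_counts(cell.counts, rng)
    mk = lambda c, cid: CellState(c, params.V0, 0.0,
                                  sample_cell_cycle(params.tau, params.lam, rng),
                                  cid, parent_id=cell.cell_id)
    return mk(c1, -1), mk(c2, -2)


def enforce_constant_population(n_present: int, rng: np.random.Generator) -> int:
    """Index of the cell to wash out, uniform over all present (newborns
    included).  Call with the momentary census N+1 after a division."""
    if n_present < 2:
        raise ValueError("removal requires a momentary census of at least 2")
    return int(rng.integers(n_present))


# ---------------------------------------------------------------------------
# the driver
# ---------------------------------------------------------------------------

class SsaResult(NamedTuple):
    pop: PopulationState
    trajectory: Trajectory
    log: EventLog
    stopped: bool               # stop-threshold crossed
    stop_time: float            # min (nan when not stopped)
    n_events: int


def advance(pop: PopulationState, t_end: float, params: ParameterSet,
            rng: np.random.Generator, *,
            sample_every: float = 1.0,
            record_species: bool = False,
            constant_n: bool = True,
            clamp_aext_nM: float | None = None,
            stop_threshold_nM: float | None = None,
            stop_direction: int = 1,
            log_reactions: int = 0,
            max_events: float = 1e12) -> SsaResult:
    """Advance the population to ``t_end`` minutes of simulated time.

    Division events act as deterministic time barriers interleaved with the
    SSA clock.  The trajectory is sampled every ``sample_every`` minutes.
    ``clamp_aext_nM`` freezes the external autoinducer at a fixed
    concentration (single-cell first-passage protocol); ``stop_threshold_nM``
    halts the run when cell 0 crosses that GFP concentration in
    ``stop_direction`` (+1 upward, −1 downward).  ``max_events`` is the
    runaway guard: on overflow the partial result is returned cleanly.
    """
    if t_end < pop.t_min:
        raise ValueError("t_end must not precede the current time")
    pk = pack_params(params)
    rs = _kernel.seed_rng(int(rng.integers(2**62)))
    clamp = clamp_aext_nM is not None
    clamp_conc = float(clamp_aext_nM) if clamp else 0.0
    stop_dir = int(stop_direction) if stop_threshold_nM is not None else 0
    stop_conc = float(stop_threshold_nM) if stop_threshold_nM is not None else 0.0

    log = EventLog()
    cap = int(log_reactions)
    log_t = np.empty(cap)
    log_cell = np.empty(cap, dtype=np.int64)
    log_ch = np.empty(cap, dtype=np.int64)
    log_n = np.zeros(1, dtype=np.int64)

    times, ids_rec, gfp_rec, vol_rec, aext_rec, sp_rec = [], [], [], [], [], []

    def record():
        times.append(pop.t_min)
        ids_rec.append(pop.ids.copy())
        gfp_rec.append(pop.x[:, I_GFP].copy())
        vol_rec.append(pop.volumes(params))
        aext_rec.append(pop.aext)
        if record_species:
            sp_rec.append(pop.x.copy())

    record()
    aext_box = np.array([pop.aext])
    next_sample = pop.t_min + sample_every
    total_events = 0
    stopped = False
    stop_time = math.nan

    while pop.t_min < t_end - 1e-9 and not stopped:
        t_div = float(np.min(pop.birth + pop.taui))
        i_div = int(np.argmin(pop.birth + pop.taui))
        barrier = min(next_sample, t_div, t_end)
        t_reached, n_ev, stop_flag, neg = _kernel.advance_interval(
            pop.x, aext_box, pop.birth, pop.taui, pop.t_min, barrier, pk, rs,
            clamp, clamp_conc, stop_dir, stop_conc,
            log_t, log_cell, log_ch, log_n, max_events - total_events)
        if neg:
            raise RuntimeError("negative count detected in the SSA kernel")
        pop.t_min = t_reached
        pop.aext = float(aext_box[0])
        total_events += n_ev
        if stop_flag:
            stopped = True
            stop_time = t_reached
            break
        if total_events >= max_events:
            break
        if barrier == t_div and t_reached >= t_div - 1e-9:
            _divide_at(pop, i_div, params, rng, log, constant_n)
        if pop.t_min >= next_sample - 1e-9 and pop.t_min < t_end - 1e-9:
            record()
            next_sample += sample_every
    if not times or abs(times[-1] - pop.t_min) > 1e-9:
        record()

    for k in range(int(log_n[0])):
        log.events.append(Event(float(log_t[k]), "reaction",
                                int(log_cell[k]), (int(log_ch[k]),)))
    log.events.sort(key=lambda e: e.time)

    traj = Trajectory(
        times=np.array(times),
        ids=np.array(ids_rec),
        gfp_counts=np.array(gfp_rec),
        volumes=np.array(vol_rec),
        aext=np.array(aext_rec),
        species=np.array(sp_rec) if record_species else None,
    )
    return SsaResult(pop, traj, log, stopped, stop_time, total_events)


def _divide_at(pop: PopulationState, i: int, params: ParameterSet,
               rng: np.random.Generator, log: EventLog,
               constant_n: bool) -> None:
    mother_id = int(pop.ids[i])
    c1, c2 = _partition_counts(pop.x[i], rng)
    id1, id2 = pop.next_id, pop.next_id + 1
    pop.next_id += 2
    t = pop.t_min
    # daughter 1 takes the mother's slot
    pop.x[i] = c1
    pop.birth[i] = t
    pop.taui[i] = sample_cell_cycle(params.tau, params.lam, rng)
    pop.ids[i] = id1
    log.append(Event(t, "division", mother_id, (id1, id2)))
    if constant_n:
        k = enforce_constant_population(pop.n_cells + 1, rng)
        if k == pop.n_cells:        # the appended daughter 2 is washed out
            log.append(Event(t, "removal", id2, ()))
            return
        removed_id = int(pop.ids[k])  # daughter 2 replaces the removed cell
        pop.x[k] = c2
        pop.birth[k] = t
        pop.taui[k] = sample_cell_cycle(params.tau, params.lam, rng)
        pop.ids[k] = id2
        log.append(Event(t, "removal", removed_id, ()))
    else:
        pop.x = np.vstack([pop.x, c2[None, :]])
        pop.birth = np.append(pop.birth, t)
        pop.taui = np.append(pop.taui,
                             sample_cell_cycle(params.tau, params.lam, rng))
        pop.ids = np.append(pop.ids, id2)


def fpt_single_cell(params: ParameterSet, cA_star: float,
                    initial_conc: np.ndarray, threshold_nM: float,
                    horizon_min: float, rng: np.random.Generator,
                    direction: int = 1,
                    sample_every: float = 10.0) -> tuple[float, bool]:
    """First passage time of a single cell at clamped external autoinducer.

    The cell grows and divides; the followed lineage continues through one
    daughter chosen uniformly at random (with N = 1 the constant-census
    removal rule implements exactly this).  Returns ``(fpt_min, censored)``;
    censored runs report the horizon as a lower bound.
    """
    p1 = params.replace(N=1, cA_star=cA_star)
    pop = population_from_concentrations(initial_conc, p1, rng)
    res = advance(pop, horizon_min, p1, rng,
                  sample_every=sample_every,
                  clamp_aext_nM=cA_star,
                  stop_threshold_nM=threshold_nM,
                  stop_direction=direction)
    if res.stopped:
        return float(res.stop_time), False
    return float(horizon_min), True
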