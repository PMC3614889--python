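"""Statistics over simulation output: state classification, bimodality and
precision of the quorum-sensing switch, first-passage-time summaries,
population averages and lineage trees.

A cell is "high" when its GFP concentration reaches half of the
deterministic full-induction steady state (GFP_max at cA* = 100 nM).  A
population snapshot is bimodal when neither the low nor the high
subpopulation reaches 90%; the autoinducer range [cA*_b1, cA*_b2] over
which snapshots are bimodal defines the precision of the switch as
1/(cA*_b2 − cA*_b1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .ssa import EventLog, Trajectory

#: classification threshold on normalized GFP; ties go to "high"
HIGH_THRESHOLD = 0.5
#: unimodality criterion: a snapshot is bimodal when neither fraction
#: reaches this proportion
UNIMODAL_FRACTION = 0.9


def classify_state(gfp_norm) -> np.ndarray | str:
    """Classify normalized GFP level(s) as ``"low"`` or ``"high"``.

    Normalization is by the deterministic GFP_max, not a per-run maximum.
    A value exactly at the half-maximum threshold classifies as high.
    """
    arr = np.asarray(gfp_norm, dtype=float)
    if np.any(arr < 0):
        raise ValueError("normalized GFP must be non-negative")
    out = np.where(arr >= HIGH_THRESHOLD, "high", "low")
    return out.item() if np.isscalar(gfp_norm) or arr.ndim == 0 else out


@dataclass
class ResponseDistribution:
    """Per-cell normalized GFP snapshot at one autoinducer concentration."""

    cA_star: float
    gfp_norm: np.ndarray

    def __post_init__(self):
        self.gfp_norm = np.asarray(self.gfp_norm, dtype=float)

    @property
    def fraction_high(self) -> float:
        return float(np.mean(self.gfp_norm >= HIGH_THRESHOLD))

    @property
    def fraction_low(self) -> float:
        return 1.0 - self.fraction_high

    @property
    def bimodal(self) -> bool:
        """Neither subpopulation reaches 90% (a tie counts as unimodal)."""
        return max(self.fraction_low, self.fraction_high) < UNIMODAL_FRACTION


class BimodalityRange(NamedTuple):
    cA_b1: float        # nM, onset of bimodality
    cA_b2: float        # nM, completion of the collective switch
    precision: float    # 1/(cA_b2 − cA_b1), infinite when the range is empty

    @property
    def width(self) -> float:
        return self.cA_b2 - self.cA_b1


def _interp_crossing(x0, x1, f0, f1, level):
    if f1 == f0:
        return x1
    return x0 + (level - f0) / (f1 - f0) * (x1 - x0)


def bimodality_range(distributions: Sequence[ResponseDistribution]
                     ) -> BimodalityRange:
    """Bimodality interval [cA*_b1, cA*_b2] from snapshots sorted by cA*.

    cA*_b1 is the lowest concentration at which the low fraction drops below
    90% and cA*_b2 the lowest at which the high fraction reaches 90%;
    both are linearly interpolated between grid points so widths can be
    reported below grid resolution.  An empty range yields infinite
    precision.
    """
    ca = np.array([d.cA_star for d in distributions], dtype=float)
    if np.any(np.diff(ca) <= 0):
        raise ValueError("distributions must be sorted by increasing cA_star")
    f_low = np.array([d.fraction_low for d in distributions])
    f_high = np.array([d.fraction_high for d in distributions])

    below = f_low < UNIMODAL_FRACTION
    if not below.any():
        return BimodalityRange(math.nan, math.nan, math.inf)
    j = int(np.argmax(below))
    if j == 0:
        b1 = ca[0]
    else:
        b1 = _interp_crossing(ca[j - 1], ca[j], f_low[j - 1], f_low[j],
                              UNIMODAL_FRACTION)

    reached = f_high >= UNIMODAL_FRACTION
    # completion: first concentration at/after the onset where the high
    # fraction reaches 90%
    k = None
    for idx in range(j, len(ca)):
        if reached[idx]:
            k = idx
            break
    if k is None:
        b2 = ca[-1]          # switch not completed on this grid
    elif k == 0:
        b2 = ca[0]
    else:
        b2 = _interp_crossing(ca[k - 1], ca[k], f_high[k - 1], f_high[k],
                              UNIMODAL_FRACTION)
    width = b2 - b1
    return BimodalityRange(float(b1), float(b2),
                           math.inf if width <= 0 else 1.0 / width)


# ---------------------------------------------------------------------------
# first passage times
# ---------------------------------------------------------------------------

@dataclass
class FptSample:
    """First-passage-time draws at one autoinducer concentration."""

    cA_star: float
    fpt_h: np.ndarray           # hours; censored entries hold the horizon
    censored: np.ndarray        # boolean flags

    def __post_init__(self):
        self.fpt_h = np.asarray(self.fpt_h, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        if self.fpt_h.shape != self.censored.shape:
            raise ValueError("fpt and censoring arrays must align")


class FptSummary(NamedTuple):
    mfpt_h: float               # mean of uncensored draws
    q10_h: float
    q90_h: float
    censored_fraction: float
    mfpt_is_lower_bound: bool   # true when any draw was censored


def mfpt_and_quantiles(sample: FptSample) -> FptSummary:
    """MFPT and the 10%/90% quantiles of the first-passage distribution.

    Quantiles use the inverse empirical CDF (no interpolation), with
    censored draws entering at their horizon value (lower bounds).  The
    MFPT averages the uncensored draws and is flagged biased-low whenever
    censoring occurred; an all-censored sample reports the horizon itself
    as the lower bound.
    """
    cfrac = float(np.mean(sample.censored))
    uncensored = sample.fpt_h[~sample.censored]
    if uncensored.size == 0:
        mfpt = float(np.min(sample.fpt_h))   # "> horizon"
    else:
        mfpt = float(np.mean(uncensored))
    q10 = float(np.quantile(sample.fpt_h, 0.10, method="inverted_cdf"))
    q90 = float(np.quantile(sample.fpt_h, 0.90, method="inverted_cdf"))
    return FptSummary(mfpt, q10, q90, cfrac, cfrac > 0)


# ---------------------------------------------------------------------------
# population averages
# ---------------------------------------------------------------------------

class PopulationAverage(NamedTuple):
    times: np.ndarray           # min
    mean: np.ndarray            # mean normalized GFP over cells, realizations
    sem: np.ndarray             # standard error of the mean


def population_average(trajectories: Iterable[Trajectory],
                       gfp_max_nM: float) -> PopulationAverage:
    """Mean normalized GFP over cells and realizations on the shared grid."""
    trajs = list(trajectories)
    if not trajs:
        raise ValueError("no trajectories given")
    t0 = trajs[0].times
    mats = []
    for tr in trajs:
        if tr.times.shape != t0.shape or not np.allclose(tr.times, t0):
            raise ValueError("trajectories must share the same output grid")
        mats.append(tr.gfp_norm(gfp_max_nM))
    stacked = np.concatenate(mats, axis=1)    # (T, cells × realizations)
    mean = stacked.mean(axis=1)
    sem = stacked.std(axis=1, ddof=1) / math.sqrt(stacked.shape[1])
    return PopulationAverage(t0.copy(), mean, sem)


# ---------------------------------------------------------------------------
# lineage trees
# ---------------------------------------------------------------------------

def lineage_edges(log: EventLog, trajectory: Trajectory | None = None,
                  gfp_max_nM: float | None = None) -> pd.DataFrame:
    """Parent→child edge table of the division events in an event log.

    Each division contributes two edges.  Cells later washed out by the
    dilution protocol are flagged ``truncated``.  When a trajectory is
    given, each child carries its time-averaged normalized GFP over the
    samples in which it was present.
    """
    divisions = log.of_kind("division")
    removals = {e.cell_id: e.time for e in log.of_kind("removal")}
    end_times: dict[int, float] = {}
    for e in divisions:           # a cell ends when it divides...
        end_times[e.cell_id] = e.time
    for cid, t in removals.items():   # ...or when it is washed out
        end_times[cid] = t

    gfp_of: dict[int, float] = {}
    if trajectory is not None:
        norm = (trajectory.gfp_norm(gfp_max_nM)
                if gfp_max_nM else trajectory.gfp_nM())
        ids_flat = trajectory.ids.ravel()
        vals_flat = np.asarray(norm).ravel()
        sums: dict[int, float] = {}
        counts: dict[int, int] = {}
        for cid, v in zip(ids_flat, vals_flat):
            sums[int(cid)] = sums.get(int(cid), 0.0) + float(v)
            counts[int(cid)] = counts.get(int(cid), 0) + 1
        gfp_of = {cid: sums[cid] / counts[cid] for cid in sums}

    rows = []
    for e in divisions:
        for child in e.detail:
            rows.append({
                "parent": e.cell_id,
                "child": int(child),
                "birth_h": e.time / 60.0,
                "end_h": end_times.get(int(child), math.nan) / 60.0
                if int(child) in end_times else math.nan,
                "truncated": int(child) in removals,
                "gfp_norm": gfp_of.get(int(child), math.nan),
            })
    df = pd.DataFrame(rows, columns=["parent", "child", "birth_h", "end_h",
                                     "truncated", "gfp_norm"])
    known = set(int(c) for e in divisions for c in e.detail)
    known |= {e.cell_id for e in divisions}
    orphan = [cid for cid in removals if cid not in known]
    # removals of founder cells (present from t=0) are legitimate; an orphan
    # is a removal of an id that never existed
    if trajectory is not None:
        seen = set(int(i) for i in np.unique(trajectory.ids))
        bad = [cid for cid in orphan if cid not in seen]
        if bad:
            raise ValueError(f"orphan removal events for unknown cells {bad}")
    return df
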