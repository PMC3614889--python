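"""Deterministic population-average model of the quorum-sensing switch.

All cells share their cytoplasm in a single volume ``Vc_tot``; species are
described by concentrations (nM).  Cell growth at doubling time τ adds a
dilution term −γ·c (γ = ln2/τ) to every intracellular species, while DNA
duplication adds +γ·(c_DNA + c_DNA·C2) to the free-promoter equation so that
the total gene-copy concentration stays constant.  The medium exchanges
autoinducer with the cytoplasm by passive diffusion and with the dilution
buffer through the chemostat influx/efflux, which drives the external
concentration toward the control value ``cA_star``.

State vector (nM): [mRNA_luxR, mRNA_luxIgfp, luxR, luxIgfp, A, C, C2,
DNA_free, DNA_bound, A_ext].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.integrate import solve_ivp

from .parameters import ParameterSet

ODE_SPECIES = ("mRNA_luxR", "mRNA_luxIgfp", "luxR", "luxIgfp", "A",
               "C", "C2", "DNA_free", "DNA_bound", "A_ext")
GFP_INDEX = 3
A_INDEX = 4
AEXT_INDEX = 9

RTOL = 1e-8
ATOL = 1e-10


def ode_rhs(state: np.ndarray, params: ParameterSet) -> np.ndarray:
    """Mass-action time derivatives (nM/min) of the population-average model.

    The dimerization flux carries the 1/2 symmetry factor of the
    identical-reactant channel 2C → C₂ (see docs/methods.md); the reverse
    flux returns two complexes per event.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (10,):
        raise ValueError("state must have 10 components")
    if np.any(y < -1e-9):
        raise ValueError("negative concentrations rejected")
    return _rhs(0.0, y, params)


def _rhs(t, y, p: ParameterSet, clamp_external: bool = False):
    mR, mI, R, I, A, C, C2, DNAf, DNAb, Aext = y
    gam = p.gamma
    bind = (p.k1_minus / p.Kd1) * R * A - p.k1_minus * C
    dim = 0.5 * (p.k2_minus / p.Kd2) * C * C - p.k2_minus * C2
    prom = (p.klux_minus / p.Kdlux) * C2 * DNAf - p.klux_minus * DNAb
    return np.array([
        p.alphaR * p.kR * DNAf + p.kR * DNAb - (p.dmR + gam) * mR,
        p.alphaI * p.kI * DNAf + p.kI * DNAb - (p.dmI + gam) * mI,
        p.pR * mR - bind - (p.dR + gam) * R,
        p.pI * mI - (p.dI + gam) * I,
        p.kA * I - bind + p.D * (Aext - A) - (p.dA + gam) * A,
        bind - 2.0 * dim - (p.dC + gam) * C,
        dim - prom - (p.dC2 + gam) * C2,
        -prom + gam * DNAb,          # -γ·DNAf + γ·(DNAf + DNAb)
        prom - gam * DNAb,
        0.0 if clamp_external else
        p.r * p.D * (A - Aext) - p.dA * Aext
        + gam * (p.cA_star * p.Vtot / p.Vext - Aext),
    ])


@dataclass
class OdeTrajectory:
    """Dense solution of one deterministic run."""

    params: ParameterSet
    t_min: np.ndarray          # solver time points, min
    states: np.ndarray         # (n_times, 10) concentrations, nM
    _interp: object = None     # scipy dense-output callable

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def at(self, t_min) -> np.ndarray:
        """Interpolated state(s) at the given time(s) in minutes."""
        if self._interp is None:
            raise ValueError("trajectory has no dense output")
        out = self._interp(np.asarray(t_min, dtype=float))
        return out.T if out.ndim == 2 else out

    def gfp(self, t_min) -> np.ndarray:
        """LuxI::GFP (GFP for lux01) concentration in nM at the given times."""
        return np.atleast_2d(self.at(t_min))[..., GFP_INDEX].squeeze()


def zero_state(params: ParameterSet) -> np.ndarray:
    """All species zero except the (free) promoter at ``c_dna_tot``."""
    y = np.zeros(10)
    y[7] = params.c_dna_tot
    return y


def integrate(initial: np.ndarray, duration_min: float,
              params: ParameterSet,
              clamp_external: bool = False) -> OdeTrajectory:
    """Integrate the model with a stiff solver (LSODA, rtol 1e-8).

    A zero duration returns a trajectory holding only the initial state.
    ``clamp_external`` freezes the external autoinducer concentration (the
    boundary condition of the single-cell first-passage protocol).
    """
    y0 = np.asarray(initial, dtype=float)
    if duration_min < 0:
        raise ValueError("duration must be non-negative")
    if duration_min == 0:
        return OdeTrajectory(params, np.array([0.0]), y0[None, :].copy())
    sol = solve_ivp(_rhs, (0.0, duration_min), y0,
                    args=(params, clamp_external),
                    method="LSODA", rtol=RTOL, atol=ATOL, dense_output=True)
    if not sol.success:
        raise RuntimeError(
            f"ODE integration failed: {sol.message}; last state {sol.y[:, -1]}")
    return OdeTrajectory(params, sol.t, sol.y.T, sol.sol)


@lru_cache(maxsize=128)
def _basal_cached(p0: ParameterSet, pre_hours: float) -> tuple:
    return tuple(integrate(zero_state(p0), pre_hours * 60.0, p0).final_state)


def basal_state(params: ParameterSet, pre_hours: float = 10.0) -> np.ndarray:
    """Non-induced state: pre-equilibration at cA* = 0 from the empty state.

    Establishes the basal expression level of all species before any
    induction protocol is applied.  The population-average model is
    intensive (independent of N at fixed cell density), so results are
    cached per parameterization.
    """
    p0 = params.replace(cA_star=0.0, N=1)
    return np.array(_basal_cached(p0, pre_hours))


@lru_cache(maxsize=128)
def _induced_cached(p0: ParameterSet, cA_star: float, hours: float) -> tuple:
    p = p0.replace(cA_star=cA_star)
    return tuple(integrate(np.array(_basal_cached(p0, 10.0)),
                           hours * 60.0, p).final_state)


def induced_state(params: ParameterSet, cA_star: float = 100.0,
                  hours: float = 100.0) -> np.ndarray:
    """Fully induced state: long induction at saturating autoinducer."""
    return np.array(_induced_cached(params.replace(cA_star=0.0, N=1),
                                    cA_star, hours))


def steady_state(cA_star: float, branch_initial: str, params: ParameterSet,
                 induction_hours: float = 100.0) -> tuple[np.ndarray, bool]:
    """State after a long induction from the designated branch.

    ``branch_initial`` is ``"low"`` (non-induced basal state) or ``"high"``
    (state obtained after 100 h at cA* = 100 nM).  Returns the terminal
    state and a convergence flag (relative GFP change < 1e-6 per hour over
    the final hour).  Non-convergence is flagged, never raised.
    """
    if cA_star < 0:
        raise ValueError("cA_star must be non-negative")
    if branch_initial == "low":
        y0 = basal_state(params)
    elif branch_initial == "high":
        y0 = induced_state(params)
    else:
        raise ValueError("branch_initial must be 'low' or 'high'")
    return steady_state_from(y0, cA_star, params, induction_hours)


def steady_state_from(initial: np.ndarray, cA_star: float,
                      params: ParameterSet,
                      induction_hours: float = 100.0) -> tuple[np.ndarray, bool]:
    """Long induction at fixed ``cA_star`` from an arbitrary initial state."""
    p = params.replace(cA_star=cA_star)
    traj = integrate(initial, induction_hours * 60.0, p)
    g_end = traj.gfp(traj.t_min[-1])
    g_before = traj.gfp(traj.t_min[-1] - 60.0)
    denom = abs(g_end) if g_end else 1.0
    converged = abs(g_end - g_before) / denom < 1e-6
    return traj.final_state, bool(converged)


def gfp_max(params: ParameterSet) -> float:
    """Normalization constant: deterministic steady-state GFP at cA* = 100 nM.

    All "normalized GFP" values across the package divide by this number.
    """
    return float(induced_state(params)[GFP_INDEX])


def time_to_steady_state(params: ParameterSet, cA_star: float = 100.0,
                         tolerance: float = 0.05,
                         horizon_hours: float = 100.0) -> float:
    """Hours until GFP enters and remains within ``tolerance`` of its
    terminal value, starting from the non-induced state.
    """
    p = params.replace(cA_star=cA_star)
    traj = integrate(basal_state(params), horizon_hours * 60.0, p)
    ts = np.linspace(0.0, horizon_hours * 60.0, 20001)
    g = traj.gfp(ts)
    g_final = g[-1]
    outside = np.abs(g - g_final) > tolerance * abs(g_final)
    if not outside.any():
        return 0.0
    return float(ts[np.nonzero(outside)[0][-1] + 1] / 60.0)


def deterministic_fpt(cA_star: float, threshold: float, params: ParameterSet,
                      horizon_hours: float = 200.0) -> float:
    """First time (minutes) the deterministic trajectory from the low state
    crosses ``threshold × GFP_max``; ``inf`` when no crossing occurs within
    the horizon and the trajectory has converged below the threshold.

    Inside the bistable region the deterministic system cannot jump, so the
    first passage time from the low branch is infinite.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    if threshold == 0.0:
        return 0.0
    target = threshold * gfp_max(params)
    p = params.replace(cA_star=cA_star)
    traj = integrate(basal_state(params), horizon_hours * 60.0, p)
    ts = np.linspace(0.0, horizon_hours * 60.0, 40001)
    g = traj.gfp(ts)
    above = g >= target
    if above.any():
        i = int(np.argmax(above))
        if i == 0:
            return 0.0
        # linear refinement inside the bracketing interval
        t0, t1 = ts[i - 1], ts[i]
        g0, g1 = g[i - 1], g[i]
        return float(t0 + (target - g0) / (g1 - g0) * (t1 - t0))
    _, converged = steady_state_from(traj.final_state, cA_star, params, 1.0)
    return math.inf if converged else math.nan
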