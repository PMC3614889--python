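"""Parameter handling for the LuxR/LuxI quorum-sensing switch models.

All rates are per minute, volumes in cubic micrometres and concentrations in
nanomolar.  The canonical parameterization describes the synthetic *lux01*
(no autoinducer synthase; pure GFP reporter) and *lux02* (luxI::gfp fusion)
constructs grown at constant density under a chemostat-like dilution protocol.

The burst sizes ``bR`` and ``bI`` tune the transcription/translation noise of
LuxR and LuxI::GFP at a *fixed* mean protein production rate: the maximum
protein synthesis flux per gene copy is held at 200 min⁻¹ (LuxR) and
50 min⁻¹ (LuxI::GFP) by recomputing the transcription rates ``kR = 200/bR``,
``kI = 50/bI`` and the translation rates ``pR = bR·dmR``, ``pI = bI·dmI``
whenever a burst size changes.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

#: molecules per nM per μm³ (Avogadro's number × 1e-9 mol/L × 1e-15 L/μm³)
MOLECULES_PER_NM_UM3 = 0.6022

#: maximum LuxR protein production rate per gene copy, min⁻¹ (= kR·bR)
LUXR_MAX_EXPRESSION = 200.0
#: maximum LuxI::GFP protein production rate per gene copy, min⁻¹ (= kI·bI)
LUXI_MAX_EXPRESSION = 50.0

#: autoinducer synthesis rate per LuxI molecule for the lux02 construct, min⁻¹
KA_LUX02 = 0.04

CONSTRUCTS = ("lux01", "lux02")


@dataclass(frozen=True)
class ParameterSet:
    """Rate constants and geometry of the quorum-sensing switch.

    Primary fields follow the model's standard symbols.  Derived quantities
    (``kR``, ``kI``, ``pR``, ``pI``, ``gamma``, ``Vext`` ...) are exposed as
    properties so they can never fall out of sync with the primaries.
    """

    construct: str = "lux01"

    # -- complex formation ------------------------------------------------
    Kd1: float = 100.0        # nM, LuxR–autoinducer dissociation constant
    k1_minus: float = 10.0    # min⁻¹, LuxR·A unbinding rate
    Kd2: float = 20.0         # nM, LuxR·A dimerization dissociation constant
    k2_minus: float = 1.0     # min⁻¹, (LuxR·A)₂ dissociation rate
    Kdlux: float = 200.0      # nM, (LuxR·A)₂ – lux promoter dissociation constant
    klux_minus: float = 10.0  # min⁻¹, promoter unbinding rate

    # -- gene expression ---------------------------------------------------
    bR: float = 20.0          # LuxR burst size (dimensionless)
    bI: float = 20.0          # LuxI::GFP burst size (dimensionless)
    alphaR: float = 0.001     # basal/activated transcription ratio, luxR
    alphaI: float = 0.01      # basal/activated transcription ratio, luxI::gfp
    dmR: float = 0.347        # min⁻¹, luxR mRNA degradation
    dmI: float = 0.347        # min⁻¹, luxI::gfp mRNA degradation

    # -- degradation -------------------------------------------------------
    dA: float = 0.001         # min⁻¹, autoinducer (inside and outside cells)
    dC: float = 0.002         # min⁻¹, LuxR·A complex
    dC2: float = 0.002        # min⁻¹, (LuxR·A)₂ dimer
    dR: float = 0.002         # min⁻¹, LuxR protein
    dI: float = 0.01          # min⁻¹, LuxI::GFP protein

    # -- transport and growth ----------------------------------------------
    D: float = 10.0           # min⁻¹, membrane diffusion rate of A
    tau: float = 45.0         # min, mean cell-cycle duration
    lam: float = 0.8          # deterministic weight of the cell cycle, ∈[0,1]
    V0: float = 1.5           # μm³, cell volume at birth
    cN: float = 5e-4          # cells per μm³ (5·10⁸ cells/mL)
    N: int = 100              # number of cells

    # -- protocol ----------------------------------------------------------
    cA_star: float = 0.0      # nM, exogenous autoinducer control concentration

    def __post_init__(self) -> None:
        if self.construct not in CONSTRUCTS:
            raise ValueError(f"unknown construct {self.construct!r}; expected one of {CONSTRUCTS}")
        if self.bR <= 0 or self.bI <= 0:
            raise ValueError("burst sizes bR, bI must be positive")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lambda must lie in [0, 1], got {self.lam}")
        if self.tau <= 0:
            raise ValueError("cell-cycle duration tau must be positive")
        if self.V0 <= 0 or self.cN <= 0:
            raise ValueError("V0 and cN must be positive")
        if self.N < 1:
            raise ValueError("N must be at least 1")
        for name in ("Kd1", "k1_minus", "Kd2", "k2_minus", "Kdlux", "klux_minus",
                     "alphaR", "alphaI", "dmR", "dmI", "dA", "dC", "dC2", "dR",
                     "dI", "D", "cA_star"):
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name} must be non-negative")
        if self.Vext <= 0:
            raise ValueError("external volume Vtot - N·V0 must be positive")

    # -- derived quantities -------------------------------------------------

    @property
    def kA(self) -> float:
        """Autoinducer synthesis rate per LuxI molecule (0 for lux01)."""
        return 0.0 if self.construct == "lux01" else KA_LUX02

    @property
    def kR(self) -> float:
        """luxR transcription rate, min⁻¹ (burst-size compensated)."""
        return LUXR_MAX_EXPRESSION / self.bR

    @property
    def kI(self) -> float:
        """luxI::gfp transcription rate, min⁻¹ (burst-size compensated)."""
        return LUXI_MAX_EXPRESSION / self.bI

    @property
    def pR(self) -> float:
        """luxR translation rate, min⁻¹."""
        return self.bR * self.dmR

    @property
    def pI(self) -> float:
        """luxI::gfp translation rate, min⁻¹."""
        return self.bI * self.dmI

    @property
    def gamma(self) -> float:
        """Dilution rate ln(2)/tau, min⁻¹."""
        return math.log(2.0) / self.tau

    @property
    def Vtot(self) -> float:
        """Total culture volume, μm³ (set by N and the cell density cN)."""
        return self.N / self.cN

    @property
    def Vc_tot(self) -> float:
        """Pooled cytoplasmic volume of the population at birth size, μm³."""
        return self.N * self.V0

    @property
    def Vext(self) -> float:
        """External (medium) volume, μm³."""
        return self.Vtot - self.Vc_tot

    @property
    def r(self) -> float:
        """Cytoplasm-to-medium volume ratio Vc_tot/Vext."""
        return self.Vc_tot / self.Vext

    @property
    def c_dna_tot(self) -> float:
        """Total gene-copy concentration in the pooled cytoplasm, nM.

        One promoter per cell, N cells in ``Vc_tot``.
        """
        return self.N / (MOLECULES_PER_NM_UM3 * self.Vc_tot)

    # -- convenience ---------------------------------------------------------

    def replace(self, **changes) -> "ParameterSet":
        """Return a copy with the given primary fields replaced."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        """Primary fields plus derived rates, for manifests and provenance."""
        d = dataclasses.asdict(self)
        d.update(kA=self.kA, kR=self.kR, kI=self.kI, pR=self.pR, pI=self.pI,
                 gamma=self.gamma, Vtot=self.Vtot, Vext=self.Vext,
                 Vc_tot=self.Vc_tot, r=self.r, c_dna_tot=self.c_dna_tot)
        return d


_PRIMARY_FIELDS = {f.name for f in dataclasses.fields(ParameterSet)}


def build_parameter_set(overrides: Mapping[str, float] | None = None,
                        construct: str = "lux01") -> ParameterSet:
    """Build a :class:`ParameterSet` from canonical defaults plus overrides.

    Parameters
    ----------
    overrides
        Mapping of primary field names to values.  Unknown keys raise
        ``KeyError``.  Derived quantities (``kR``, ``pR``, ``gamma`` ...)
        cannot be overridden directly: change the burst sizes or ``tau``.
    construct
        ``"lux01"`` (no autoinducer synthesis, kA = 0) or ``"lux02"``.
    """
    overrides = dict(overrides or {})
    unknown = set(overrides) - _PRIMARY_FIELDS
    if unknown:
        raise KeyError(f"unknown parameter name(s): {sorted(unknown)}")
    overrides.setdefault("construct", construct)
    return ParameterSet(**overrides)


# ---------------------------------------------------------------------------
# unit conversions
# ---------------------------------------------------------------------------

def concentration_to_count(c_nM: float, volume_um3: float) -> int:
    """Convert a concentration (nM) in a volume (μm³) to a molecule count.

    Rounds to the nearest integer; the continuous value is
    ``c · 0.6022 · V``.
    """
    if c_nM < 0:
        raise ValueError("concentration must be non-negative")
    if volume_um3 <= 0:
        raise ValueError("volume must be positive")
    return int(round(c_nM * MOLECULES_PER_NM_UM3 * volume_um3))


def count_to_concentration(n: float, volume_um3: float) -> float:
    """Convert a molecule count to a concentration in nM."""
    if n < 0:
        raise ValueError("count must be non-negative")
    if volume_um3 <= 0:
        raise ValueError("volume must be positive")
    return n / (MOLECULES_PER_NM_UM3 * volume_um3)


# ---------------------------------------------------------------------------
# cell-cycle sampling
# ---------------------------------------------------------------------------

def sample_cell_cycle(tau: float, lam: float, rng: np.random.Generator) -> float:
    """Draw a cell-cycle duration τᵢ = λτ + (1−λ)·Exp(mean=τ).

    The deterministic component λτ acts as a hard minimum duration; the
    exponential component models division triggered by a Poisson process.
    The ensemble mean is τ and the standard deviation (1−λ)τ.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    return lam * tau + (1.0 - lam) * rng.exponential(tau)
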