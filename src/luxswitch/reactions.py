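"""Reaction catalog of the LuxR/LuxI switch.

The regulatory scheme per cell:

* transcription of ``luxR`` and ``luxI::gfp`` from the free promoter at the
  basal rates ``αR·kR``, ``αI·kI`` and from the activator-bound promoter at
  the full rates ``kR``, ``kI``;
* translation at ``pR``, ``pI``;
* autoinducer synthesis by LuxI at ``kA`` (zero for *lux01*);
* LuxR + A ⇌ LuxR·A (forward ``k1−/Kd1``, reverse ``k1−``);
* 2 LuxR·A ⇌ (LuxR·A)₂ (forward ``k2−/Kd2`` with the combinatorial
  ``n(n−1)/2`` factor for identical reactants, reverse ``k2−``);
* (LuxR·A)₂ + DNA ⇌ DNA·(LuxR·A)₂ (forward ``klux−/Kdlux``, reverse ``klux−``);
* first-order degradation of every species; complexes degrade whole, without
  releasing LuxR or autoinducer;
* membrane diffusion A → A_ext at ``D`` and A_ext → cell *i* at ``D·rᵢ(t)``;
* chemostat exchange of the medium: influx of exogenous autoinducer at
  ``γ·cA*·Vtot`` molecules/min and efflux of A_ext at ``γ`` per molecule.

Propensity conventions (count space): order-0 rates are molecules/min;
order-1 propensities are ``k·n``; order-2 propensities are
``k/(f·V)·n₁·n₂`` for distinct reactants and ``k/(f·V)·n(n−1)/2`` for the
symmetric dimerization channel, with ``f = 0.6022`` molecules·nM⁻¹·μm⁻³ and
``V`` the current cell volume (second-order propensities therefore scale as
``V0/V`` during growth).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .parameters import MOLECULES_PER_NM_UM3, ParameterSet

#: per-cell species, in canonical order
SPECIES = ("mRNA_luxR", "mRNA_luxIgfp", "luxR", "luxIgfp", "A",
           "C", "C2", "DNA_free", "DNA_bound")

I_MR, I_MI, I_R, I_I, I_A, I_C, I_C2, I_DNAF, I_DNAB = range(9)


@dataclass(frozen=True)
class ReactionChannel:
    """One reaction channel: stoichiometry, rate constant and scope.

    ``scope`` is ``"cell"`` for intracellular channels, ``"exchange"`` for
    membrane diffusion (coupling a cell to the medium) and ``"external"``
    for channels acting on the medium pool only.  ``delta_ext`` is the
    change in the external autoinducer count when the channel fires.
    """

    name: str
    reactants: dict = field(default_factory=dict)
    products: dict = field(default_factory=dict)
    rate_constant: float = 0.0
    order: int = 1
    volume_dependent: bool = False
    symmetric: bool = False
    scope: str = "cell"
    delta_ext: int = 0

    def __post_init__(self):
        for sto in (self.reactants, self.products):
            for sp, nu in sto.items():
                if sp not in SPECIES:
                    raise ValueError(f"unknown species {sp!r}")
                if not (isinstance(nu, int) and nu >= 0):
                    raise ValueError("stoichiometries must be non-negative integers")
        if (self.order == 2) != self.volume_dependent:
            raise ValueError("exactly the order-2 channels are volume dependent")

    def delta(self) -> dict:
        """Net per-cell stoichiometric change when the channel fires."""
        out: dict = {}
        for sp, nu in self.products.items():
            out[sp] = out.get(sp, 0) + nu
        for sp, nu in self.reactants.items():
            out[sp] = out.get(sp, 0) - nu
        return {sp: d for sp, d in out.items() if d != 0}


def reaction_catalog(params: ParameterSet) -> list[ReactionChannel]:
    """Return every reaction channel of the model for one cell plus the
    external pool.  Deterministic: the same parameters give the same catalog.
    """
    p = params
    f = MOLECULES_PER_NM_UM3
    ch = [
        ReactionChannel("transcription_luxR_basal", {"DNA_free": 1},
                        {"DNA_free": 1, "mRNA_luxR": 1}, p.alphaR * p.kR),
        ReactionChannel("transcription_luxI_basal", {"DNA_free": 1},
                        {"DNA_free": 1, "mRNA_luxIgfp": 1}, p.alphaI * p.kI),
        ReactionChannel("transcription_luxR_activated", {"DNA_bound": 1},
                        {"DNA_bound": 1, "mRNA_luxR": 1}, p.kR),
        ReactionChannel("transcription_luxI_activated", {"DNA_bound": 1},
                        {"DNA_bound": 1, "mRNA_luxIgfp": 1}, p.kI),
        ReactionChannel("translation_luxR", {"mRNA_luxR": 1},
                        {"mRNA_luxR": 1, "luxR": 1}, p.pR),
        ReactionChannel("translation_luxI", {"mRNA_luxIgfp": 1},
                        {"mRNA_luxIgfp": 1, "luxIgfp": 1}, p.pI),
        ReactionChannel("synthesis_A", {"luxIgfp": 1},
                        {"luxIgfp": 1, "A": 1}, p.kA),
        ReactionChannel("binding_R_A", {"luxR": 1, "A": 1}, {"C": 1},
                        p.k1_minus / p.Kd1, order=2, volume_dependent=True),
        ReactionChannel("unbinding_C", {"C": 1}, {"luxR": 1, "A": 1}, p.k1_minus),
        ReactionChannel("dimerization", {"C": 2}, {"C2": 1},
                        p.k2_minus / p.Kd2, order=2, volume_dependent=True,
                        symmetric=True),
        ReactionChannel("undimerization", {"C2": 1}, {"C": 2}, p.k2_minus),
        ReactionChannel("promoter_binding", {"C2": 1, "DNA_free": 1},
                        {"DNA_bound": 1}, p.klux_minus / p.Kdlux,
                        order=2, volume_dependent=True),
        ReactionChannel("promoter_unbinding", {"DNA_bound": 1},
                        {"C2": 1, "DNA_free": 1}, p.klux_minus),
        ReactionChannel("diffusion_out", {"A": 1}, {}, p.D,
                        scope="exchange", delta_ext=+1),
        ReactionChannel("diffusion_in", {}, {"A": 1}, p.D,
                        scope="exchange", delta_ext=-1),
        ReactionChannel("degradation_A", {"A": 1}, {}, p.dA),
        ReactionChannel("degradation_mRNA_luxR", {"mRNA_luxR": 1}, {}, p.dmR),
        ReactionChannel("degradation_mRNA_luxI", {"mRNA_luxIgfp": 1}, {}, p.dmI),
        ReactionChannel("degradation_luxR", {"luxR": 1}, {}, p.dR),
        ReactionChannel("degradation_luxI", {"luxIgfp": 1}, {}, p.dI),
        ReactionChannel("degradation_C", {"C": 1}, {}, p.dC),
        ReactionChannel("degradation_C2", {"C2": 1}, {}, p.dC2),
        # external pool
        ReactionChannel("influx_Aext", {}, {}, p.gamma * p.cA_star * f * p.Vtot,
                        order=0, scope="external", delta_ext=+1),
        ReactionChannel("efflux_Aext", {}, {}, p.gamma,
                        scope="external", delta_ext=-1),
        ReactionChannel("degradation_Aext", {}, {}, p.dA,
                        scope="external", delta_ext=-1),
    ]
    return ch
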