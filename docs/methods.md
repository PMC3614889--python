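# Methods

## Model

The circuit couples nine per-cell species — the two mRNAs, LuxR (R),
LuxI::GFP (I), free intracellular autoinducer (A), the LuxR·A complex (C),
its dimer (LuxR·A)₂ (C₂), and the free/bound promoter — to one shared
external autoinducer pool (A_ext). Complex formation steps are reversible
with forward rate constants written as the dissociation rate over the
dissociation constant (k₋/K_d); degradation is first-order for every
species, and complexes degrade whole, destroying the bound autoinducer.
Only *lux02* synthesizes autoinducer (k_A = 0.04 min⁻¹ per LuxI; 0 for
*lux01*).

Units are minutes, μm³ and nM internally; counts and concentrations convert
through f = 0.6022 molecules·nM⁻¹·μm⁻³.

### Default parameters

Dissociation constants K_d1 = 100 nM, K_d2 = 20 nM, K_dlux = 200 nM with
reverse rates 10, 1 and 10 min⁻¹; burst sizes b_R = b_I = 20 with
k_R = 200/b_R, k_I = 50/b_I, p_R = b_R·d_mR, p_I = b_I·d_mI
(d_mR = d_mI = 0.347 min⁻¹); basal/activated expression ratios
α_R = 0.001, α_I = 0.01; degradation d_A = 0.001, d_C = d_C2 = d_R = 0.002,
d_I = 0.01 min⁻¹; membrane diffusion D = 10 min⁻¹; cell cycle τ = 45 min
with deterministic weight λ = 0.8; birth volume V₀ = 1.5 μm³; density
c_N = 5·10⁸ cells/mL, so V_tot = N/c_N (2·10⁻⁴ μL at N = 100) and
V_ext = V_tot − N·V₀. The dilution rate is γ = ln2/τ. One promoter per
cell sets the pooled gene-copy concentration c_DNA,tot = 1/(f·V₀) ≈ 1.107
nM in the deterministic model.

### The dimerization convention

For the identical-reactant channel 2C → C₂ the stochastic propensity uses
the combinatorial pair count, (k₂₋/K_d2)/(fV) · n_C(n_C−1)/2, and the
deterministic flux is the matching mean-field limit (k₂₋/K_d2)·C²/2. The
effective equilibrium constant of dimerization is therefore 2·K_d2. We
adopted this convention — rather than the textbook mass-action reading
k_f·C² with k_f = k₂₋/K_d2 — because it is the standard way a Gillespie
code turns the printed rate constants into propensities, and because only
this convention reproduces the canonical deterministic bistable region
(2.5–14.5 nM for lux01; the plain reading gives an upper boundary near
10 nM). Both engines share the convention, so they agree in their common
limit.

## Deterministic engine

The population shares one cytoplasmic volume V_c,tot = N·V₀ held constant
by the dilution protocol; every intracellular species carries a −γc
dilution term, and the free-promoter equation carries +γ(c_DNA + c_DNA·C₂)
so the total gene-copy concentration is exactly conserved. The medium
exchanges autoinducer with the cytoplasm at D (in) / r·D (out, with
r = V_c,tot/V_ext) and with the dilution buffer through
dc_Aext/dt += γ(c*_A·V_tot/V_ext − c_Aext). Integration uses LSODA at
rtol 10⁻⁸/atol 10⁻¹⁰ with dense output.

Conventions used throughout the analyses:

* **Non-induced state**: 10 h pre-equilibration at c*_A = 0 from the empty
  state (only DNA present). The medium therefore starts autoinducer-free;
  induction includes the ≈1/γ ≈ 65 min filling of the bath, identically in
  both engines.
* **Fully induced state**: 100 h at c*_A = 100 nM from the non-induced
  state. Its GFP concentration defines GFP_max, the normalization for all
  "normalized GFP" values and for the half-maximum classification
  threshold.
* **Steady state**: 100 h of induction, flagged converged when the
  relative GFP change over the final hour is below 10⁻⁶.
* **Bistable region**: the outermost concentrations where 100-h
  integrations from the two states settle more than 0.1·GFP_max apart,
  refined by bisection (default 0.05 nM).

The model is intensive in N (the density c_N is what matters), so derived
states are cached per parameterization.

## Stochastic engine

All reactions of all cells plus the external channels form one global
Gillespie system. Cell volumes grow exponentially between divisions;
second-order propensities carry the instantaneous V₀/Vᵢ factor. Because
every reaction is much faster than volume growth (≥ minutes⁻¹ vs 1/τ),
propensities are held at their last-evaluated volume until the owning cell
next fires or a barrier is crossed (output-grid tick, division) — the
standard adiabatic treatment; the staleness is bounded by the output
interval (≤ 1.6%/min of the second-order rates).

Divisions are deterministic barriers: when a cell's clock reaches its
individually sampled τᵢ, any promoter-bound dimer is detached into the
free pool, each free species is split Binomial(n, ½), each daughter gets
one promoter, volume V₀, clock 0 and a fresh τᵢ. Under the dilution
protocol one cell — chosen uniformly among the N+1 present, newborns
included — is removed per birth, keeping the census at N. External
autoinducer influx/efflux (γ·c*_A·f·V_tot and γ per molecule) and medium
degradation run as explicit channels; the diffusion of external molecules
into cells is pooled into a single channel with the receiving cell drawn
proportionally to its volume (exactly equivalent to per-cell channels).

Random numbers come from a dedicated xoshiro256** stream seeded from the
caller's generator, so runs are bit-reproducible per seed across platforms;
divisions and partitioning draw from the caller's numpy generator.

The first-passage protocol follows a single cell with the external pool
clamped at the control concentration (the propensity of inward diffusion
becomes D·f·c*_A·Vᵢ); at division the followed lineage continues through
one daughter chosen uniformly — with N = 1 the constant-census removal
rule implements exactly this. Runs that have not crossed the half-maximum
threshold at the horizon are censored there and reported as lower bounds;
the MFPT averages uncensored draws and is flagged biased-low under
censoring. Quantiles use the inverse empirical CDF without interpolation.

## Relation between the two engines

The descriptions agree exactly — in expectation for linear subsystems, and
trajectory-wise in the small-noise (b → 0) limit — when growth-dilution is
absent, and the test suite verifies both statements against independent
oracles (closed-form exponential decay; a piecewise-linear count ODE with
division halving). With growth they differ by a known gene-dosage factor:
the stochastic model expresses from one promoter copy per cell (production
per cell constant through the cycle), while the population-average model
holds the gene *concentration* constant, which is equivalent to
continuously replicating dosage. Per-cell steady concentrations in the
stochastic model therefore sit ≈ ln2 below the deterministic curve.
Normalized-GFP classifications are robust to this: activated cells sit at
0.6–1.0 of GFP_max against a basal level of ≈0.01.

Two consequences worth knowing. First, stochastic activation is slower
than deterministic activation at all burst sizes above the critical
concentration — the promoter/dimer nucleation step is discrete and does
not vanish as b → 0 — which is precisely the non-trivial MFPT behavior the
analyses quantify. Second, at low control concentrations (≈10–25 nM) a
*clamped* single cell's activated state is only metastable at b_R = 20:
sequestration of autoinducer by the large LuxR pool leaves so few free
intracellular molecules (tens) that occupancy fluctuations can drive the
cell back below threshold within hours. In the full population protocol at
moderate concentrations (e.g. 50 nM) activation is irreversible over the
experiment and inherited by descendants, which is what the lineage
analyses assert.

## Scaled-down study conditions

Full-scale experiments use N = 100 cells, 10 realizations and 2.5-nM
concentration grids. The test battery runs the same protocols on a scaled
system: N = 8–24 cells at the *same* density (V_tot shrinks with N, so
volumes, per-cell counts and all propensities are unchanged), 1–2
realizations, and 5–15-nM grids; first-passage campaigns use 30–100
replicates instead of 10³. This preserves the per-cell physics and hence
orderings and qualitative features (bimodal-window ordering across burst
sizes, the 10 h → 100 h window shrinkage, the MFPT noise crossover), at
the cost of coarser fraction estimates (quantized at 1/16 with 16 pooled
cells) and earlier-activation order statistics: the earliest activation
among ~50 cells falls within 8 h where a 1000-cell pool shows ≈3 h.
Washout drift is also stronger at small N — the high subpopulation
performs a neutral Moran walk with N-dependent fixation times — which is
why population-dynamics checks use N = 24 rather than 8.

What passing these tests does *not* show: agreement with real colonies
(the generator emulates a well-stirred chemostat, no spatial structure, no
nutrient effects, fixed rate constants), nor full-scale quantitative widths
(measured here to grid/sampling precision only).

## Numerical choices and degenerate inputs

Counts round half-away-from-zero when concentrations are mapped to
molecules; zero-duration runs return the initial state; an empty bimodality
range reports infinite precision; ties at the classification threshold go
to "high", and a snapshot exactly at the 90% criterion counts as unimodal.
The SSA guards against runaway event rates with a configurable cap and
returns the partial result cleanly. Deterministic first-passage times are
infinite inside the bistable region (reported as such only when the
trajectory has converged below threshold by the horizon).

## Known limitations

The high/low expression ratio is structurally bounded by 1/α_I = 100 times
the promoter occupancy, so it lands at ≈96 rather than a clean 100. With
the canonical d_A = 0.001 min⁻¹ the dilution protocol holds the free
autoinducer at γ/(γ+d_A) ≈ 94% of the control value (2% accuracy requires
d_A ≪ γ); upon activation, LuxR sequestration lowers free A substantially
(at 50 nM control: ≈40 nM outside, ≈22 nM inside cells). Deactivation
dynamics of clamped single cells at low concentrations are fragile, as
described above.
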