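# Methods

## Model and assumptions

The network is ED glycolysis reduced to glucose uptake, the ED
reactions, pyruvate decarboxylase/alcohol dehydrogenase ethanol
fermentation, and CO₂/H⁺ free exchange: 14 reactions, of which five
(EDA, GAPDH, PGK, PGM, ENO) are reversible and are split into
irreversible forward/backward pairs with mirrored atom maps. The
system is at metabolic and isotopic steady state; every pool is well
mixed. Stoichiometry leaves a single free net-flux direction, so the
net flux map is one scale parameter anchored by the measured glucose
uptake (ethanol excretion is twice the uptake by construction and
enters the fit as a second rate measurement).

Atom transitions are data, not code: YAML files with arrow-notation
equations and atom-letter strings, one file per traced element
(carbon, hydrogen). A letter pairs one substrate atom slot with one
product atom slot; validation enforces that the pairing is a total
bijection (atom conservation) and that every internal species is
balanceable and reachable. Hydrogen positions are named by the carbon
they ride (H4 = the hydrogen on glucose C4). Each `NetworkModel`
carries one traced element; the fitter joins one model per element
over a shared reaction list.

Hydrogen bookkeeping, shipped as editable model data:

- ZWF transfers the G6P C1 hydride to the reduced-cofactor pool;
- EDD's dehydration sends the 6PG C2/C3 hydrogens to solvent;
- EDA retains KDPG C4-H on GAP C1;
- GAPDH transfers GAP C1-H to the cofactor pool, and its backward
  direction redraws a hydride from that pool;
- ENO loses the 2PG C2-H to water forward and draws a water hydrogen
  (natural ²H abundance) backward;
- hydrogens that no shipped tracer can label (e.g. PEP C3-H at PYK)
  are routed to the solvent sink.

Water-derived hydrogens always enter at natural deuterium abundance:
the cell-water pool is effectively infinite and unlabeled.

**Carrier pool.** The NAD(P)H hydrides from ZWF and GAPDH are pooled
into a single well-mixed steady-state species (`REDH`) drained by
alcohol dehydrogenase and by backward GAPDH. The lumping is a
deliberate design choice: with strictly separate single-source pools,
the hydride returned by backward GAPDH carries exactly the
steady-state labeling of the hydride removed, and GAPDH exchange
becomes invisible to every tracer. Pooling the (differently labeled)
ZWF hydride provides the dilution that makes the [4-²H] diagnostic —
loss of the GAP C1 deuteron through GAPDH exchange — informative.
*Z. mobilis*' broad-specificity alcohol dehydrogenases make a shared
effective hydride sink reasonable. A model option
(`carriers_unlabeled`) forces the pool to natural abundance instead.

## EMU simulation and its oracle

MIDs are computed with the elementary-metabolite-unit decomposition:
the minimal set of atom subsets needed for the observed metabolites is
derived by pulling target atoms back through the atom maps; balances
are stratified by EMU size and solved as dense linear systems
`A(v)X = B(v)Y` per size (networks here are tiny; dense LU). Cleavage
products pull subsets of their precursor; condensations become
convolution nodes over independent pools. Tracer inputs are mixtures
of position-labeled components — labeled positions fully enriched,
all other positions at natural abundance — and free-exchange species
enter at natural abundance. Incoming flux vectors are checked for
steady state (max imbalance ≤ 1e-8 × max flux); a singular balance
system raises an error naming the affected metabolites.

The independent oracle (`enumerate_isotopomers`) solves the full
2ⁿ-state positional-isotopomer balance by Gauss–Seidel sweeps with a
projection of every pool back onto the probability simplex after each
update. The projection matters: the bilinear condensation terms (two
co-derived substrate pools multiplying) make the mass-conserving
fixed point of the raw sweep unstable once exchange fluxes are large,
and the unprojected iteration converges to a spurious mass-deficient
solution. With the projection the oracle agrees with the EMU cascade
to ~1e-12 on all shipped fixtures, on randomized toy networks, and at
exchange fluxes 25× the net flux. Simulated measurement envelopes
carry the natural abundance of all untraced atoms in the full ion
formula (binomial/multinomial per element, IUPAC abundances kept in
one editable table), truncated at n_traced + 4 mass shifts and
renormalized (truncation error < 1e-6 for the formulas in scope).

## Measurement model and weighting

Labeling data are fitted *uncorrected* for natural abundance — the
simulation carries the natural envelope instead — while display-side
analyses (labeling fractions, reverse-flux diagnostics) use
natural-abundance-corrected MIDs (nonnegative least squares against
the untraced-atom envelope matrix, then renormalized; plain inversion
can go negative on noisy data). Tracer impurity is not corrected
either: the glucose feed is modeled as labeled + unlabeled inputs
with the unlabeled fraction a fitted parameter.

Per-bin measurement SDs combine three arms:
`max(replicate SD, max |observed − theoretical| over naturally
labeled standards, 0.003)`. The 0.3% floor and the natural-standard
arm absorb systematic errors of the measurement process. One such
error is intrinsic to fraction data: measured MIDs are clipped at
zero and renormalized, which biases large bins low by roughly the
clipped noise mass. The synthetic generator reproduces this process
and also emits natural-standard reference measurements, so the fitted
weights are derived exactly as they would be from real data. A
consequence is that the χ² gate is conservative: SSR sits well below
its degrees of freedom and essentially no correct-model fit is
rejected, while the nominal 5% false-rejection bound is respected.
Exact two-sided 95% calibration is unattainable under this
measurement process without abandoning the three-arm precision rule.

Fits are replicate-resolved: each replicate MID is a separate
weighted measurement (fitting replicate means against per-replicate
SDs would deflate SSR by the replicate count). Mass bins at or below
1e-4 measured fraction are excluded from both the residuals and the
degrees-of-freedom count ("non-zero MIDs"), and one bin per MID is
discounted for the sum-to-one constraint:
dof = Σ(non-zero bins − 1) + rates − parameters.

## Fitting, gating, intervals

Free parameters: the uptake scale `u`, one exchange coordinate
`t = e/(e + u) ∈ [0, 0.995]` per reversible reaction (forward flux =
net + e, backward = e; for a reaction whose net flux equals the
uptake, `t` is exactly J⁻/J⁺), and the unlabeled-feed fraction
`f ∈ [0, 0.5]`. Optimization is bound-constrained trust-region least
squares (numerically approximated Jacobian, ftol 1e-10, xtol 1e-8)
from a deterministic center start plus uniform random starts in the
transformed coordinates; batches of starts repeat until the best SSR
improves by less than a relative 1e-6 over a full batch. All starts
and their SSRs are logged; a fixed seed reproduces the fit exactly.

The χ² gate defaults to the one-sided upper test (accept iff
SSR ≤ χ²₀.₉₅(dof)); a two-sided mode is available. Profile 95%
intervals fix one parameter, re-optimize all others, and expand
outward (doubling steps, then bisection) until the profiled SSR
crosses SSR_opt + 3.841 (χ²₀.₉₅ with 1 df); a side whose box bound
never crosses is reported open at the bound. Profiles re-optimize
nuisance parameters (true profile likelihood). Flux-ratio and ΔG
intervals are monotone transforms of the profiled exchange
coordinate. The two-condition comparison fits each condition
separately and pooled (one parameter set, all experiments and rates)
and reports three verdicts.

## Thermodynamics

ΔG = RT·ln(J⁻/J⁺) with R = 8.314e-3 kJ·mol⁻¹·K⁻¹ and T = 303.15 K
(30 °C cultures; configurable). J⁻ = 0 returns −∞, flagged fully
forward. The concentration route is the thermodynamic identity
ΔG = ΔG°′ + RT·ln(Q) (the package treats the relation between ΔG°′
and Q as additive; any other reading is dimensionally wrong) for
reactions whose reversibility labeling cannot resolve. Condition
differences use a z-approximation with SE = interval width / (2·1.96)
per condition — a declared artifact choice, since profile intervals
are not exactly normal; its p-values are not asserted to equal any
published significance calls.

## Omics statistics

Metabolomics normalization divides raw signal by OD₆₀₀ (or by a
matched U-¹³C internal-standard signal); statistics run on log₂
values. Fold changes divide each sample by the control-replicate mean
and average the log₂ ratios per time point (average-of-logs).
Proteomics keeps features observed in strictly more than 50% of
samples. Tests: one-way repeated-measures ANOVA over time (classical
partitioning, no sphericity correction, complete cases — a replicate
missing any time point is dropped for that feature); a mixed
two-way ANOVA (condition between, growth stage within) for the
continuous metabolomics contrast; Welch two-sided t tests for the
continuous proteomics contrast. BH step-up FDR; significance =
FC ≥ 1.5 (fold scale, depletion symmetric) AND FDR ≤ 0.05, inclusive
thresholds by default. Overrepresentation is a one-sided
hypergeometric tail per term over a user-supplied term map, BH
adjusted. The closed-form RM-ANOVA is cross-checked against
statsmodels' AnovaRM in the tests.

## Synthetic ground truth

The condition presets place GAPDH at −1.617 (N₂) and −0.897 kJ/mol
(NH₄⁺) — converted to exchange fluxes at 303.15 K — with uptake
normalized to 100 units and a 1% unlabeled glucose admixture. The
other reversible reactions get intermediate near-equilibrium values
typical of lower glycolysis (EDA −3.0/−2.5, PGK −1.5/−1.2,
PGM −1.0/−0.8, ENO −1.8/−1.5 kJ/mol for N₂/NH₄⁺), uniformly more
favorable under N₂ so the presets encode the qualitative ordering the
analysis is meant to detect. MID noise is additive Gaussian at the
0.3% floor, clipped at zero and renormalized, three replicates; rates
carry 5% SDs. The ¹⁵N generator gives each pool first-order labeling
p(t) = p_max(1 − e^(−kt))·e^(−rt); the glutamine-like preset
(k = 30 h⁻¹, p_max = 0.980, r = 0.022 h⁻¹) realizes a fully labeled
fraction of 0.95 at 15 min decaying to 0.88 at 2 h. The re-entry rate
r is phenomenological (label loss through protein turnover), not a
mechanistic degradation model. Omics tables are log-normal with
per-feature base levels (log₂ SD 2), planted log₂ effects of 1–3
(random sign), residual log₂ SD 0.5, OD₆₀₀ metadata, the study's
replicate designs (5 + 5 continuous; 3 treatment + 2 control time
courses with effects ramping in), and optional missing-at-random
dropout. Every generator is a pure function of its configuration and
seed.

What the generators do *not* emulate: chromatographic artifacts,
intensity-dependent missingness, between-batch drift, compartmented
pools, or kinetic isotope effects. Passing tests therefore
demonstrate correctness of the inference chain under its stated
assumptions, not robustness to those real-data pathologies.

## Study sizes and numerics

The repeated-dataset studies use 100 seeds for CI coverage and χ²
calibration, 50 for two-condition discrimination, 100 for omics null
FDR, and 5 × 500 features for sensitivity; the acceptance script uses
30/20/40 to keep a full from-scratch run within a few minutes on one
CPU. Linear solves are dense; the isotopomer oracle iterates to
1e-13 with a 200k-sweep cap and refuses metabolites beyond 12 traced
atoms. Exchange coordinates are capped at 0.995 (J⁻/J⁺ ≈ 200:1 is
indistinguishable from equilibrium at the shipped noise level).

## Known limitations

- The hydrogen atom maps are defensible defaults, marked provisional;
  solvent-exchange assignments beyond the enumerated ones are not
  modeled.
- PGK and PGM exchanges are only weakly identified by the shipped
  tracer panel (their diagnostics overlap through the 3PG/2PG pools);
  their profile intervals are accordingly wide.
- The χ² gate is conservative under the three-arm precision model
  (see above); gate acceptance near 100% on correct models is
  expected behavior, not evidence of miscalibration in the rejection
  direction.
- The z-test on ΔG differences and the designated reverse-flux bins
  are package choices where the underlying procedures are
  schematic; both are shipped as data/configurable code for audit.
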