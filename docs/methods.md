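# Methods

## The core model

The built-in model is a deliberately small (44 reactions, 44 metabolites,
21 genes) but exactly balanced representation of central catabolism in a
cytochrome-lacking methanogen. It contains the C1 trunk of methanogenesis
(Fwd → Ftr → Mch → Mtd/Hmd → Mer → Mtr → Mcr), heterodisulfide reduction
(Hdr), the hydrogenases Fru/Frc (F₄₂₀-reducing), Hmd (H₂-dependent
methylene-H₄MPT dehydrogenase), the Eha/Ehb energy-converting
(Na⁺-coupled) hydrogenases, formate dehydrogenase (Fdh), GAPOR, CODH/ACS
carbon fixation, acetate activation, pyruvate synthesis (POR), a
Na⁺-coupled ATP synthase, an ATP-hydrolysis maintenance reaction
(`rxn00062[c0]`) and a lumped biomass reaction. Compartments are tagged
`[c0]`/`[e0]`, exchanges follow the `EX_{metabolite}[e0]` convention,
positive exchange flux is secretion, and all fluxes are mmol·gDCW⁻¹·h⁻¹.

Carrier scaffolds (ferredoxin, F₄₂₀, H₄MPT, methanofuran, CoA) use
abstract element symbols (`Fd`, `Fo`, `Pt`, `Mf`, `Qa`) with explicit
hydrogen and charge bookkeeping, so every internal and transport reaction
passes strict element- and charge-balance checking; only exchanges and
pseudo-reactions (biomass, ledger drain) are exempt. Electron-carrier
topology: F₄₂₀ serves Mtd, Mer, Fdh, Fru, Frc and the lumped GAPDH/PGK
step; ferredoxin serves Fwd, Hdr, Eha/Ehb, GAPOR, CODH/ACS and POR.

### Sodium economy (a calibrated choice)

What the essentiality argument requires is only that Eha's
Na⁺-per-ferredoxin ratio equals Mtr's Na⁺-per-methane ratio, so that a
methanogenic cycle relying on Eha for its ferredoxin is ion-neutral. We
set both to 2 (Mtr exports 2 Na⁺/CH₄, Eha/Ehb translocate 2
Na⁺/ferredoxin) and the ATP synthase to 4 Na⁺/ATP (`na_per_atp`,
configurable). Hydrogenotrophic growth then nets 0.5 ATP per CH₄ minus
anabolic overhead — in the physiological range for methanogens living
near the thermodynamic limit.

### Formate metabolism

Fdh reduces F₄₂₀ (irreversibly, formate + F₄₂₀ → CO₂ + F₄₂₀H₂); a
formate-fed Hdr complex (`HdrFdh`, GPR `hdrA and fdhA`) bifurcates two
formate-derived electron pairs to the heterodisulfide and ferredoxin.
Vhu/Vhc are represented at GPR level — the H₂-fed bifurcating Hdr carries
`hdrA and (vhuU or vhcG)` — because the knockout validation operates at
hydrogenase-complex granularity, not at the level of separate
electron-carrier fluxes.

### Anabolism and biosynthetic H₂

Biomass consumes 0.75 pyruvate equivalents plus NH₃, H₂S, phosphate and
GAM ATP. The anabolic chain (CO₂ → acetyl-CoA via CODH/ACS → pyruvate via
POR, each step plus the extra Fwd flux consuming one reduced ferredoxin)
costs 2.25 mmol ferredoxin per gDCW, which at steady state must come from
the anaplerotic Eha/Ehb (or GAPOR when open). The biomass reaction also
releases 2.35 mmol H₂ per gDCW — biosynthesis is a net H₂ producer — and
this small term (< 1% of catabolic H₂ turnover) is load-bearing: in
hydrogenase-free genotypes on formate it is the only substrate left for
Eha, and it is precisely why the model predicts growth for the formate
Δ5/Δ6-hydrogenase mutants that die in vivo. The precursor coefficient is
kept small so catabolic stoichiometry dominates flux ratios; the lumped
biomass is not a carbon-accounting device.

### GAPOR

The reconstruction ships GAPOR open (it exists in the wild-type genome);
knockout simulations constrain it to zero flux per case — wild-type
expression cannot rescue hydrogenase-free growth — except for the two
GAPOR-overexpressing suppressor genotypes, which get it unbounded. A
lumped ATP-consuming GAPDH/PGK step closes the triose loop so GAPOR can
transduce F₄₂₀H₂ electrons to ferredoxin at 1 ATP per ferredoxin.

### Media presets

`H2_CO2`, `formate`, `McNA` (H₂ + CO₂ + acetate) and `acetate_only`, with
free exchange of water, protons and Na⁺ and modest caps on NH₃, H₂S and
phosphate. Uptake caps (H₂ 250, CO₂ 70, formate 100, acetate 10
mmol·gDCW⁻¹·h⁻¹) are plumbing, chosen with enough headroom that the
chemostat states at the trained maintenance values (≈ 165 mmol H₂ at
D = 0.09 h⁻¹) remain feasible even under reading noise; growth-rate
*ratios*, which every prediction in the package relies on, are
insensitive to them. Na⁺ crosses the membrane only through Mtr, Eha/Ehb
and the ATP synthase — a free Na⁺ uniporter would short-circuit the
energy economy.

## FBA engine

Two-stage LP on split non-negative flux variables (v = p − q), solved
with scipy's HiGHS. Stage 1 maximizes the objective; stage 2 fixes it to
within `tol_fix` (10⁻⁶) and minimizes Σ|vᵢ| (`l1`, default — a pure LP,
deterministic with reaction columns ordered by sorted id) or Σvᵢ² (`l2`,
a small SLSQP-solved QP, behind a flag). The reported objective is the
stage-1 optimum; the returned flux vector realizes it within `tol_fix`.
Pseudo-reactions (biomass, the free-energy drain) are excluded from the
total-flux objective — their magnitude is bookkeeping, not flux. Flux
couplings with absolute-value terms (the Eha/Ehb cap) become linear rows
over the split variables. Solver feasibility tolerance is 10⁻⁹;
infeasible and unbounded problems are reported as status, never as silent
zeros. A brute-force oracle (`fba_oracle_small`) enumerates all basic
feasible solutions for models of ≤ 12 reactions and is used to verify the
engine on seeded random toy networks.

## Knockout panel

`delete_genes` closes every reaction whose GPR evaluates false; lethality
is growth strictly below `max(0.10 × wild-type growth, 10⁻⁹)` on the same
condition. The epsilon handles conditions where the wild type itself
cannot grow (acetate only): there the bare threshold (10% of zero) would
classify everything as growing. MCC follows the standard confusion-matrix
formula with nonlethal = positive and a zero denominator mapped to 0.

The shipped validation panel (`generate_knockout_fixture`) is a
**synthetic transcription**: the original validation grid exists only as
a figure, so the fixture reconstructs an 18-genotype × 4-condition panel
at hydrogenase-complex granularity from the M. maripaludis mutant
literature, constrained to the published summary (30 observed cells,
28/30 correct, 93% accuracy, MCC 0.78, the two errors being the formate
Δ5/Δ6 hydrogenase mutants predicted nonlethal, exactly two
GAPOR-suppressor cases). Passing it shows the core model reproduces the
published error *structure*, not that locus-level genotypes were
recovered. Only the two validated suppressor cells carry
`gapor_mode="unbounded"`; the unvalidated cells of those genotypes are
simulated with GAPOR at zero like every other case.

## Thermodynamic ledger

Each exchange `A[e0] ⇌` is augmented with a coefficient ΔG_A on a
pseudo-metabolite dG, drained by `GIBBS_kJ_GDW`; the drain flux at an
optimum equals Σ ΔG_eff(i)·v_EX(i), the overall free-energy rate in
kJ·gDCW⁻¹·h⁻¹. Formation energies are referenced to 1 mM, 25 °C, pH 7,
I = 0.1 M; effective concentrations c (mM) shift them by RT·ln(c/1 mM) —
the correction uniquely consistent with a 1 mM standard state. The
bundled values for H₂, CO₂, CH₄, H₂O, formate and acetate are
Equilibrator-style group-contribution numbers and are configuration:
override them through `ThermoLedger`. Exchanged species without a
reliable estimate (H₂S, NH₃, phosphate, protons, Na⁺, water is included)
carry coefficient 0 with a warning. With the drain unbounded the
augmentation is exactly neutral for every non-thermo optimum;
`constrain_negative` bounds the drain ≤ 0, imposing the second law on the
organism as a whole. Per-reaction thermodynamic constraints are out of
scope.

## Chemostat yields and maintenance

Doubling time is implemented as t_d[min] = 60·ln2 / D[h⁻¹] — the only
dimensionally consistent reading of the printed formula, which drops the
unit conversion. The yield formula uses the measured OD₆₆₀ → dry-weight
conversion 0.462 g·l⁻¹ per OD unit by default; the historical constant
0.46 is available via `od_to_gdw` to reproduce older calculations. The
bridge from culture readings to biomass-specific flux,
(ml CH₄/min × 60 / 22.4) / (OD₆₆₀ × 0.462 × V), makes the implicit
volume and cell-density dependence explicit.

`fit_maintenance` zeroes the biomass ATP term, then for each sample fixes
growth and methane secretion and maximizes ATP hydrolysis; unweighted OLS
of the ATP optimum against growth rate gives GAM (slope) and NGAM
(intercept). Zeroing the GAM during the fit is what makes the slope the
*total* growth-associated ATP demand, so `apply_maintenance` followed by
a refit is an exact fixpoint and noise-free synthetic data return the
generating values to machine precision. Fitting and LOOCV run on the
H₂ + CO₂ medium preset.

## Synthetic data

The chemostat generator emulates H₂-limited continuous culture: nine
dilution rates evenly spaced over 0.045–0.090 h⁻¹, the model's minimum
methane secretion at each fixed growth rate, a nominal standing density
of OD₆₆₀ = 0.30 in 1 l, and multiplicative Gaussian reading noise
(default 3%) on OD and CH₄ — noise lives on instrument readings, not on
derived yields, so measured yields inherit a ≈ 4.2% relative sd and the
synthetic 95% CIs are ±1.96·√2·3%. What it does not emulate: gas-transfer
kinetics, H₂ mass-transfer limitation, replicate structure, or drift
between samples; recovery tests therefore demonstrate estimator
correctness and noise propagation, not robustness to systematic error in
real chemostat data. Toy networks are single-element conversion chains
with random parallel shortcuts, bounds and reversibility — balanced and
flux-consistent by construction, small enough for exhaustive vertex
enumeration.

## Numerical choices and edge cases

- LP tolerances: feasibility 10⁻⁹, objective fixing 10⁻⁶; flux-level
  comparisons in tests use invariants (steady state, oracle dot
  products), not exact flux vectors, because L1 optima can be degenerate.
- Lethality ties at exactly the threshold classify lethal (strict `<`).
- MCC with an empty row or column of the confusion matrix is 0.
- `adjust_for_concentration` rejects non-positive concentrations;
  `set_medium` rejects unknown exchange ids; serializers report malformed
  rows with line numbers and refuse undefined SBML species references.
- Dead-end detection is structural pruning to a fixpoint (only-produced /
  only-consumed metabolites, plus metabolites balanced by a single
  reaction). On irreversible flow networks this equals LP flux-support
  enumeration, and the tests verify that; with reversible internal loops
  pruning is deliberately weaker than a full LP blocked-reaction scan,
  which would be a solver call rather than a structural diagnostic.

## Known limitations

- The core model lumps all biosynthesis into a small precursor demand;
  absolute growth rates and yields are meaningful only through the
  GAM/NGAM parameters, and carbon balance of biomass is not modeled.
- The aceticlastic acetate activation is a 1-ATP equivalent; the real
  enzyme may be AMP-forming (2 ATP equivalents), which would shift the
  acetate energy balance without changing the 2-ferredoxin signature.
- Na⁺ stoichiometries beyond the 1:1 cycle argument are calibrated
  choices, not measured values.
- The SBML dialect is the legacy level-2 COBRA convention (kinetic-law
  bound parameters, notes-based GPRs); fbc-style level-3 files are not
  parsed.
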