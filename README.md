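# methanofba

Constraint-based simulation suite for hydrogenotrophic methanogenesis in
*Methanococcus maripaludis*, built around a compact, fully mass- and
charge-balanced core model of the cyclical methanogenic pathway. It is a
self-contained re-implementation of the simulation layer behind the iMR539
genome-scale reconstruction: flux balance analysis with secondary flux
minimization, gene-knockout phenotype prediction scored by the Matthews
correlation coefficient, an exchange-flux overall free-energy ledger, and
chemostat-based ATP-maintenance fitting with leave-one-out cross
validation — all runnable on the built-in core model and synthetic data,
no downloads required.

## The science

*M. maripaludis* is a cytochrome-lacking methanogen. Its heterodisulfide
reductase (HdrABC) conserves energy by **flavin-based electron
bifurcation**, coupling the exergonic reduction of the CoM-S-S-CoB
heterodisulfide to the endergonic reduction of ferredoxin that drives the
first step of CO₂ reduction:

```
CoB-S-S-CoM + 2 H2 + Fd_ox  ⇌  HS-CoB + HS-CoM + 2 H+ + Fd_red
```

This closes methanogenesis into a cycle: the only net ion pumping is the
Na⁺ exported by the membrane methyltransferase (Mtr), and the Na⁺-coupled
A₁A₀ ATP synthase converts that gradient into ATP. The package's core
model encodes exactly this economy, so the classical FBA machinery

```
maximize c'v   subject to   S v = 0,  v_lower ≤ v ≤ v_upper
```

(with an optional second stage minimizing Σ|vᵢ|) reproduces the headline
behaviours of the full reconstruction:

- **Bifurcation is essential** — replacing the Hdr reaction with its
  mass/charge-rebalanced, ferredoxin-free variant
  (`CoB-S-S-CoM + H2 ⇌ HS-CoB + HS-CoM`) makes each methanogenic cycle
  sodium-neutral and abolishes growth on H₂ + CO₂.
- **Aceticlastic growth is stoichiometrically forbidden** once the
  energy-converting hydrogenases Eha/Ehb are pinned to an anaplerotic
  role (|v_Eha| + |v_Ehb| ≤ 10% of methane secretion); unconstrained,
  the model grows on acetate with Eha/Ehb oxidizing ≈ 2 mol ferredoxin
  per mol CH₄.
- **Knockout phenotypes** — hydrogenase deletion genotypes across four
  media are predicted from GPR rules with a 10%-of-wild-type lethality
  threshold, scored by MCC, and the trained GAM/NGAM maintenance
  parameters are recovered from (synthetic) chemostat measurements.

## Worked example

```
$ python examples/02_bifurcation_and_acetate.py
growth on H2+CO2, bifurcating Hdr:     0.7546 1/h
growth on H2+CO2, non-bifurcating Hdr: -0.0000 1/h

acetate only, Eha/Ehb unbounded: growth 0.1207 1/h, Fd oxidized per CH4 = 1.981
acetate only, Eha/Ehb capped at 10% of CH4: growth -0.00e+00 1/h
```

The native model grows on H₂ + CO₂ (0.75 h⁻¹ at saturating uptake
bounds); without bifurcation the optimum is exactly zero. On acetate the
unconstrained model grows, with the energy-converting hydrogenases
oxidizing 1.98 ferredoxins per methane (the ≈ 2 signature of the
hypothetical aceticlastic route); with the default anaplerotic cap the
optimum drops to zero.

```
$ python examples/05_maintenance_and_loocv.py
generating truth: GAM = 169.9, NGAM = 5.0
refit from noisy data: GAM = 184.0 mmol ATP/gDCW, NGAM = 4.24 mmol ATP/gDCW/h (R^2 = 0.9781)
...
9/9 predictions within the 95% CI
```

Each `examples/*.py` script is a short narrative: build or load a small
input, run one capability, print what it computes.

A thin CLI mirrors the library (`methanofba build-core | check | fba |
knockouts | maintenance | thermo | synth`), e.g.

```
methanofba fba core --medium H2_CO2
methanofba knockouts core --threshold 0.1
```

## Scope

The full 688-reaction iMR539 reconstruction (coenzyme, lipid and
archaellin biosynthesis, likelihood-based gap filling) is distributed
separately as BioModels MODEL1607200000 and is out of scope here; the
package's TSV/SBML readers accept user-supplied models in the same
layout. See `docs/methods.md` for the model's assumptions, parameter
choices and known limitations.
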