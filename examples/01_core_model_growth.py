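"""Build the core methanogenesis model and simulate growth.

Constructs the built-in core model of hydrogenotrophic methanogenesis in
M. maripaludis (balanced stoichiometry, electron-bifurcating Hdr, Na+
energy economy), verifies mass/charge balance, and runs FBA with L1 flux
minimization on two media. Growth rate is h^-1; exchange fluxes are
mmol/gDCW/h, negative = uptake.
"""

from methanofba import build_core_model, check_mass_charge_balance, simulate_growth
from methanofba.fba import format_summary

model = build_core_model()
print(f"core model: {len(model.reactions)} reactions, "
      f"{len(model.metabolites)} metabolites, {len(model.genes)} genes")
print(f"balance violations: {len(check_mass_charge_balance(model))}")

for medium in ("H2_CO2", "formate"):
    sol = simulate_growth(model, medium=medium)
    print(f"\n--- growth on {medium} ---")
    print(format_summary(sol))

# The CH4/H2 ratio near 1:4 is the hydrogenotrophic stoichiometry
# (CO2 + 4 H2 -> CH4 + 2 H2O) plus a small anabolic overhead.
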