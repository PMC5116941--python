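"""Hydrogenase knockout panel: GPR deletions scored by MCC.

Simulates the 18-genotype x 4-condition validation panel (gene deletions
via GPR evaluation, lethality at 10% of condition-specific wild-type
growth, GAPOR zeroed except in the overexpression suppressors) and scores
the 30 experimentally characterised cells.
"""

from methanofba import build_core_model, simulate_panel, confusion_and_mcc
from methanofba.knockouts import format_panel
from methanofba.synth import generate_knockout_fixture

model = build_core_model()
cases = generate_knockout_fixture()
predictions = simulate_panel(model, cases, threshold=0.10)

scored = [p for p in predictions if p.case.observed != "unknown"]
print(format_panel(scored))

counts = confusion_and_mcc(predictions)
print(f"\nTP={counts.tp} TN={counts.tn} FP={counts.fp} FN={counts.fn}")
print(f"accuracy = {100 * counts.accuracy:.1f}%   MCC = {counts.mcc:.2f}")
# the two false positives are the formate Δ5/Δ6-hydrogenase mutants:
# in the model, biosynthetic H2 keeps Eha supplied with reductant,
# so growth is (wrongly) predicted.
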