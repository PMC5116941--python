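"""Gene deletion, panel simulation and MCC scoring."""

import math

import pytest

from methanofba import (
    delete_genes, evaluate_gpr, simulate_panel, confusion_and_mcc,
    optimize, set_medium, parse_gpr,
)
from methanofba.builder import medium_preset
from methanofba.knockouts import (
    LETHAL, NONLETHAL, UNKNOWN, ConfusionCounts, KnockoutCase,
    PanelPrediction,
)
from methanofba.synth import COMPLEX_GENES, generate_knockout_fixture


def test_empty_gpr_is_always_active():
    assert evaluate_gpr(None, {"gA"}) is True


def test_unknown_deleted_gene_warned_and_ignored():
    expr = parse_gpr("gA and gB")
    with pytest.warns(UserWarning, match="unknown genes"):
        active = evaluate_gpr(expr, {"gZ"}, known_genes={"gA", "gB"})
    assert active is True


def test_delete_absent_gene_leaves_model_unchanged(core_model):
    before = optimize(set_medium(core_model, medium_preset("H2_CO2")))
    ko = delete_genes(core_model, {"notagene"})
    for rid, rxn in core_model.reactions.items():
        assert (rxn.lower_bound, rxn.upper_bound) == (
            ko.reactions[rid].lower_bound, ko.reactions[rid].upper_bound)
    after = optimize(set_medium(ko, medium_preset("H2_CO2")))
    assert after.objective_value == pytest.approx(before.objective_value, abs=1e-9)


def test_hdr_deletion_abolishes_growth(core_model):
    ko = delete_genes(core_model, {"hdrA"})
    assert ko.reactions["Hdr[c0]"].upper_bound == 0.0
    sol = optimize(set_medium(ko, medium_preset("H2_CO2")))
    assert sol.objective_value < 1e-9


def test_single_isozyme_deletion_keeps_reaction_open(core_model):
    # Hdr's GPR needs hdrA and either Vhu or Vhc
    ko = delete_genes(core_model, {"vhuU"})
    assert ko.reactions["Hdr[c0]"].upper_bound > 0
    ko2 = delete_genes(core_model, {"vhuU", "vhcG"})
    assert ko2.reactions["Hdr[c0]"].upper_bound == 0.0


def test_deleting_superset_never_increases_growth(core_model):
    med = medium_preset("H2_CO2")
    sets = [set(), {"fruA"}, {"fruA", "frcA"}, {"fruA", "frcA", "hmdA"}]
    mus = [optimize(set_medium(delete_genes(core_model, s), med)).objective_value
           for s in sets]
    assert all(a >= b - 1e-9 for a, b in zip(mus, mus[1:]))


# -- panel ------------------------------------------------------------------

def test_wild_type_case_is_nonlethal(core_model):
    cases = [KnockoutCase("WT", frozenset(), "H2_CO2", observed=NONLETHAL)]
    (pred,) = simulate_panel(core_model, cases)
    assert pred.predicted == NONLETHAL
    assert pred.growth == pytest.approx(pred.wild_type_growth, rel=1e-6)


def test_all_hydrogenases_plus_eha_on_formate_is_lethal(core_model):
    """With every hydrogenase gone (including Eha) and GAPOR at zero flux,
    nothing can regenerate anaplerotic reduced ferredoxin on formate."""
    genes = frozenset(COMPLEX_GENES[c] for c in
                      ("Fru", "Frc", "Vhu", "Vhc", "Hmd", "Eha", "Ehb"))
    cases = [KnockoutCase("D7H2ase", genes, "formate", gapor_mode="zero")]
    (pred,) = simulate_panel(core_model, cases)
    assert pred.predicted == LETHAL
    # the GAPOR-overexpressing suppressor restores growth
    cases = [KnockoutCase("D7H2ase_sup", genes, "formate", gapor_mode="unbounded")]
    (pred,) = simulate_panel(core_model, cases)
    assert pred.predicted == NONLETHAL


def test_d5_hydrogenase_on_formate_is_the_documented_false_prediction(core_model):
    """Biosynthetic H2 keeps Eha active, so the model predicts growth where
    the real mutant dies — the model's known formate false positive."""
    genes = frozenset(COMPLEX_GENES[c] for c in ("Fru", "Frc", "Vhu", "Vhc", "Hmd"))
    cases = [KnockoutCase("D5H2ase", genes, "formate", observed=LETHAL)]
    (pred,) = simulate_panel(core_model, cases)
    assert pred.predicted == NONLETHAL
    assert pred.correct is False


def test_threshold_validation(core_model):
    cases = [KnockoutCase("WT", frozenset(), "H2_CO2")]
    with pytest.raises(ValueError):
        simulate_panel(core_model, cases, threshold=0.0)
    with pytest.raises(ValueError):
        simulate_panel(core_model, cases, threshold=1.0)


# -- confusion counts and MCC ----------------------------------------------

def _pred(observed, predicted):
    case = KnockoutCase("x", frozenset(), "H2_CO2", observed=observed)
    return PanelPrediction(case, 0.0, 1.0, predicted)


def test_perfect_mixed_predictions_give_mcc_one():
    preds = [_pred(NONLETHAL, NONLETHAL)] * 20 + [_pred(LETHAL, LETHAL)] * 10
    counts = confusion_and_mcc(preds)
    assert counts.total == 30
    assert counts.mcc == pytest.approx(1.0)
    assert counts.accuracy == pytest.approx(1.0)


def test_mcc_formula_direct_evaluation():
    # TP=20, TN=8, FP=1, FN=1 -> (160-1)/sqrt(21*21*9*9) = 159/189
    counts = ConfusionCounts(tp=20, tn=8, fp=1, fn=1)
    assert counts.mcc == pytest.approx(159.0 / 189.0)
    assert counts.mcc == pytest.approx(0.841, abs=5e-4)


def test_always_nonlethal_predictor_gets_mcc_zero():
    preds = [_pred(NONLETHAL, NONLETHAL)] * 5 + [_pred(LETHAL, NONLETHAL)] * 5
    counts = confusion_and_mcc(preds)
    assert counts.tn == counts.fn == 0
    assert counts.mcc == 0.0  # zero-denominator convention


def test_unknown_cases_are_not_scored():
    preds = [_pred(NONLETHAL, NONLETHAL), _pred(UNKNOWN, LETHAL)]
    assert confusion_and_mcc(preds).total == 1
    with pytest.raises(ValueError):
        confusion_and_mcc([_pred(UNKNOWN, LETHAL)])


def test_mcc_bounded():
    for tp, tn, fp, fn in [(5, 5, 5, 5), (1, 9, 3, 2), (0, 10, 5, 0)]:
        mcc = ConfusionCounts(tp, tn, fp, fn).mcc
        assert -1.0 <= mcc <= 1.0 and math.isfinite(mcc)
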