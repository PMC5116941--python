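"""Domain types, balance checking, media and dead-end detection."""

import numpy as np
import pytest

from methanofba import (
    MediumSpec, MetabolicModel, Metabolite, Reaction,
    check_mass_charge_balance, find_dead_ends, set_medium,
)
from methanofba.builder import medium_preset
from methanofba.fba import optimize
from methanofba.network import parse_formula
from methanofba.synth import generate_toy_network


def test_formula_parsing():
    assert parse_formula("C10H12N5O13P3") == {"C": 10, "H": 12, "N": 5, "O": 13, "P": 3}
    assert parse_formula("Fd") == {"Fd": 1}
    with pytest.raises(ValueError):
        parse_formula("C10(H2)")


def test_metabolite_compartment_must_match_id():
    with pytest.raises(ValueError):
        Metabolite("h2[c0]", formula="H2", compartment="e0")


def test_reaction_bound_order_enforced():
    with pytest.raises(ValueError):
        Reaction("r", stoich={}, lower_bound=1.0, upper_bound=-1.0)


def test_exchange_naming_invariant():
    model = MetabolicModel()
    model.add_metabolite(Metabolite("a[e0]", formula="X", compartment="e0"))
    model.add_reaction(Reaction("EX_wrong[e0]", stoich={"a[e0]": -1.0}, kind="exchange"))
    with pytest.raises(ValueError, match="EX_a"):
        model.validate()


def test_duplicate_ids_rejected(core_model):
    with pytest.raises(ValueError, match="duplicate"):
        core_model.copy().add_reaction(Reaction("Mcr[c0]", stoich={}))


# -- balance ----------------------------------------------------------------

def test_core_model_is_balanced(core_model):
    assert check_mass_charge_balance(core_model) == []


def test_injected_imbalance_is_reported(core_model):
    broken = core_model.copy()
    # H2O -> H2 loses one oxygen
    broken.add_reaction(Reaction(
        "bogus[c0]", stoich={"h2o[c0]": -1.0, "h2[c0]": 1.0}, lower_bound=0.0))
    violations = check_mass_charge_balance(broken)
    assert [v.reaction_id for v in violations] == ["bogus[c0]"]
    assert violations[0].element_residuals == {"O": -1.0}


def test_exchanges_and_pseudo_reactions_exempt(core_model):
    # exchanges are single-sided by definition and never appear
    flagged = {v.reaction_id for v in check_mass_charge_balance(core_model)}
    assert not any(r.id in flagged for r in core_model.exchanges())
    assert "biomass[c0]" not in flagged


# -- media ------------------------------------------------------------------

def test_h2_co2_preset_closes_formate_and_acetate(core_model):
    m = set_medium(core_model, medium_preset("H2_CO2"))
    assert m.reactions["EX_formate[e0]"].lower_bound == 0.0
    assert m.reactions["EX_acetate[e0]"].lower_bound == 0.0
    assert m.reactions["EX_h2[e0]"].lower_bound < 0.0


def test_acetate_only_preset(core_model):
    m = set_medium(core_model, medium_preset("acetate_only"))
    assert m.reactions["EX_h2[e0]"].lower_bound == 0.0
    assert m.reactions["EX_formate[e0]"].lower_bound == 0.0
    assert m.reactions["EX_acetate[e0]"].lower_bound < 0.0


def test_mcna_preset_allows_h2_co2_acetate(core_model):
    m = set_medium(core_model, medium_preset("McNA"))
    for rid in ("EX_h2[e0]", "EX_co2[e0]", "EX_acetate[e0]"):
        assert m.reactions[rid].lower_bound < 0.0


def test_unknown_exchange_in_medium_rejected(core_model):
    with pytest.raises(ValueError, match="unknown exchange"):
        set_medium(core_model, MediumSpec({"EX_nonsense[e0]": 5.0}))


def test_negative_uptake_rate_rejected():
    with pytest.raises(ValueError):
        MediumSpec({"EX_h2[e0]": -1.0})


# -- dead ends --------------------------------------------------------------

def _chain_without_sink():
    model = MetabolicModel()
    for mid, comp in (("a[e0]", "e0"), ("b[c0]", "c0"), ("c[c0]", "c0")):
        model.add_metabolite(Metabolite(mid, formula="X", compartment=comp))
    model.add_reaction(Reaction("EX_a[e0]", stoich={"a[e0]": -1.0},
                                lower_bound=-10, upper_bound=10, kind="exchange"))
    model.add_reaction(Reaction("t1[c0]", stoich={"a[e0]": -1.0, "b[c0]": 1.0},
                                lower_bound=0, kind="transport"))
    model.add_reaction(Reaction("r2[c0]", stoich={"b[c0]": -1.0, "c[c0]": 1.0},
                                lower_bound=0))
    return model


def test_chain_without_consumer_prunes_upstream():
    dead_mets, dead_rxns = find_dead_ends(_chain_without_sink())
    # c has no consumer; pruning then kills b and both internal reactions
    assert "c[c0]" in dead_mets and "b[c0]" in dead_mets
    assert set(dead_rxns) >= {"t1[c0]", "r2[c0]"}


def test_core_model_has_no_dead_ends(core_model):
    assert find_dead_ends(core_model) == ([], [])


def test_orphan_metabolite_is_flagged(core_model):
    broken = core_model.copy()
    broken.add_metabolite(Metabolite("orphan[c0]", formula="X", compartment="c0"))
    dead_mets, _ = find_dead_ends(broken)
    assert dead_mets == ["orphan[c0]"]


def _lp_blocked_reactions(model):
    """Flux-support oracle: a reaction is blocked iff it can carry no flux
    in any steady state (bounds widened to unit magnitude, signs kept)."""
    wide = model.copy()
    for rxn in wide.reactions.values():
        rxn.lower_bound = -1.0 if rxn.lower_bound < 0 else 0.0
        rxn.upper_bound = 1.0 if rxn.upper_bound > 0 else 0.0
    blocked = []
    for rid in wide.reaction_ids():
        hi = optimize(wide, secondary="none", objective_id=rid, maximize=True)
        lo = optimize(wide, secondary="none", objective_id=rid, maximize=False)
        if abs(hi.objective_value) < 1e-9 and abs(lo.objective_value) < 1e-9:
            blocked.append(rid)
    return blocked


@pytest.mark.parametrize("seed", range(8))
def test_dead_end_detector_agrees_with_lp_support(seed):
    model = generate_toy_network(n_reactions=int(np.random.default_rng(seed).integers(4, 13)),
                                 seed=seed)
    # intact toys carry flux everywhere
    assert find_dead_ends(model)[1] == _lp_blocked_reactions(model)
    # removing the product exchange strands the tail of the chain; the
    # comparison uses the irreversible variant, where structural pruning is
    # exact (reversible 2-cycles can hide LP-blocked exchanges from any
    # production/consumption argument)
    mutated = model.copy()
    for rxn in mutated.reactions.values():
        rxn.lower_bound = max(rxn.lower_bound, 0.0)
    mutated.reactions["EX_s[e0]"].lower_bound = -5.0
    del mutated.reactions["EX_p[e0]"]
    assert find_dead_ends(mutated)[1] == _lp_blocked_reactions(mutated)
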