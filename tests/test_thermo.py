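"""Free-energy ledger: concentration adjustment, augmentation, oracle."""

import math

import pytest

from methanofba import (
    MetabolicModel, Metabolite, Reaction,
    attach_free_energies, optimize_with_thermo, adjust_for_concentration,
    h2_sweep, optimize, set_medium,
)
from methanofba.builder import medium_preset
from methanofba.fba import STATUS_INFEASIBLE
from methanofba.thermo import ThermoLedger, free_energy_oracle


def test_reference_concentration_leaves_dgf_unchanged():
    assert adjust_for_concentration(-100.0, 1.0) == pytest.approx(-100.0)


def test_ten_millimolar_shift():
    # -100 + RT ln 10 = -100 + 2.479 * 2.3026
    assert adjust_for_concentration(-100.0, 10.0, 298.15) == pytest.approx(
        -100.0 + 8.314e-3 * 298.15 * math.log(10.0), abs=1e-9)
    assert adjust_for_concentration(-100.0, 10.0) == pytest.approx(-94.29, abs=0.01)


def test_e_millimolar_gives_rt():
    assert adjust_for_concentration(0.0, math.e, 298.15) == pytest.approx(
        8.314e-3 * 298.15, abs=1e-9)
    assert adjust_for_concentration(0.0, math.e) == pytest.approx(2.479, abs=1e-3)


def test_non_positive_concentration_rejected():
    with pytest.raises(ValueError):
        adjust_for_concentration(-100.0, 0.0)
    with pytest.raises(ValueError):
        ThermoLedger(dgf={"a[e0]": -1.0}, concentrations={"a[e0]": -2.0})


def _toy_exporter():
    """One substrate in (ΔGf unset -> 0), one product out at ΔGf = -50."""
    m = MetabolicModel()
    m.add_metabolite(Metabolite("a[e0]", formula="X", compartment="e0"))
    m.add_metabolite(Metabolite("b[e0]", formula="X", compartment="e0",
                                dgf_standard=-50.0))
    m.add_reaction(Reaction("EX_a[e0]", stoich={"a[e0]": -1.0},
                            lower_bound=-1.0, upper_bound=100, kind="exchange"))
    m.add_reaction(Reaction("conv[c0]", stoich={"a[e0]": -1.0, "b[e0]": 1.0},
                            lower_bound=0, upper_bound=100, kind="transport"))
    m.add_reaction(Reaction("EX_b[e0]", stoich={"b[e0]": -1.0},
                            lower_bound=0, upper_bound=100, kind="exchange"))
    m.objective_id = "EX_b[e0]"
    return m


def test_single_term_export_sums_to_gibbs_flux():
    with pytest.warns(UserWarning, match="no formation energy"):
        aug = attach_free_energies(_toy_exporter())
    sol = optimize_with_thermo(aug)
    assert sol.objective_value == pytest.approx(1.0, abs=1e-8)
    # the realized flux vector may sit tol_fix below the stage-1 optimum
    assert sol.total_free_energy == pytest.approx(-50.0, abs=1e-4)
    assert sol.total_free_energy == pytest.approx(
        -50.0 * sol.fluxes["EX_b[e0]"], abs=1e-9)


def test_zero_flux_solution_has_zero_gibbs():
    with pytest.warns(UserWarning):
        aug = attach_free_energies(_toy_exporter())
    aug.reactions["EX_a[e0]"].lower_bound = 0.0  # no substrate
    sol = optimize_with_thermo(aug)
    assert sol.total_free_energy == pytest.approx(0.0, abs=1e-9)


def test_double_augmentation_rejected(core_model):
    aug = attach_free_energies(core_model)
    with pytest.raises(ValueError, match="already"):
        attach_free_energies(aug)


def test_endergonic_conversion_with_second_law_is_infeasible():
    m = _toy_exporter()
    m.metabolites["b[e0]"].dgf_standard = +50.0  # product above substrate
    m.reactions["EX_b[e0]"].lower_bound = 0.5    # forced net conversion
    with pytest.warns(UserWarning):
        aug = attach_free_energies(m)
    sol = optimize_with_thermo(aug, constrain_negative=True)
    assert sol.status == STATUS_INFEASIBLE


def test_ledger_neutrality_on_core_model(core_model):
    plain = optimize(set_medium(core_model, medium_preset("H2_CO2")))
    aug = attach_free_energies(core_model)
    sol = optimize_with_thermo(aug, medium="H2_CO2")
    assert sol.objective_value == pytest.approx(plain.objective_value, abs=1e-9)


def test_oracle_identity_and_negative_dg_at_growth(core_model):
    aug = attach_free_energies(core_model)
    for medium in ("H2_CO2", "formate"):
        sol = optimize_with_thermo(aug, medium=medium)
        assert sol.ok and sol.objective_value > 0.1
        assert sol.total_free_energy < 0.0
        assert sol.total_free_energy == pytest.approx(
            free_energy_oracle(aug, sol), abs=1e-6)


def test_concentration_monotonicity(core_model):
    """Raising a product's concentration makes ΔG less negative; raising a
    substrate's makes it more negative (RT ln shifts)."""
    aug = attach_free_energies(core_model)
    base = optimize_with_thermo(aug, medium="H2_CO2").total_free_energy
    more_product = optimize_with_thermo(
        aug, medium="H2_CO2", concentrations={"ch4[e0]": 10.0}).total_free_energy
    more_substrate = optimize_with_thermo(
        aug, medium="H2_CO2", concentrations={"h2[e0]": 10.0}).total_free_energy
    assert more_product > base
    assert more_substrate < base


def test_h2_sweep_monotone_and_sorted(core_model):
    aug = attach_free_energies(core_model)
    df = h2_sweep(aug, [1.0, 0.001, 0.1, 0.01], medium="H2_CO2")
    assert list(df["h2_mM"]) == sorted(df["h2_mM"])
    # decreasing H2 concentration -> ΔG monotonically less negative
    assert df["total_free_energy"].is_monotonic_decreasing
    assert df.loc[df["h2_mM"] == 1.0, "total_free_energy"].iloc[0] == \
        pytest.approx(optimize_with_thermo(aug, medium="H2_CO2").total_free_energy,
                      rel=1e-9)


def test_h2_sweep_empty_list(core_model):
    aug = attach_free_energies(core_model)
    assert len(h2_sweep(aug, [])) == 0
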