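"""Growth-yield formulas, maintenance fitting and LOOCV."""

import pytest

from methanofba import (
    ChemostatSample, doubling_time, growth_yield, ch4_specific_flux,
    fit_maintenance, apply_maintenance, loocv_yield_predictions,
)
from methanofba.chemostat import MaintenanceFit
from methanofba.synth import ChemostatGenSpec, generate_chemostat_samples


# -- doubling time ----------------------------------------------------------

def test_two_hour_doubling():
    # D = ln2 / 2h = 0.34657 h-1 corresponds to the organism's 2 h doubling
    assert doubling_time(0.34657) == pytest.approx(120.0, rel=1e-4)


def test_slow_dilution():
    import math
    assert doubling_time(0.0693) == pytest.approx(60 * math.log(2) / 0.0693, rel=1e-12)
    assert doubling_time(0.0693) == pytest.approx(600.1, abs=0.1)


def test_doubling_time_inverse_proportionality():
    assert doubling_time(0.05) == pytest.approx(2 * doubling_time(0.10))
    with pytest.raises(ValueError):
        doubling_time(0.0)


# -- yield formula ----------------------------------------------------------

def _sample(**kw):
    base = dict(dilution_rate=0.06, od660=0.3, ch4_ml_min=2.0)
    base.update(kw)
    return ChemostatSample(**base)


def test_yield_halves_when_ch4_doubles():
    y1 = growth_yield(_sample(ch4_ml_min=1.0))
    y2 = growth_yield(_sample(ch4_ml_min=2.0))
    assert y1 == pytest.approx(2 * y2)


def test_yield_calibration_point():
    # 0.462 g/l/OD * 22400 ml/mol / td = 1  =>  td = 10348.8 min
    d = 60.0 * 0.6931471805599453 / 10348.8
    s = ChemostatSample(dilution_rate=d, od660=1.0, ch4_ml_min=1.0)
    assert growth_yield(s) == pytest.approx(1.0, rel=1e-5)


def test_historical_conversion_constant_ratio():
    y_462 = growth_yield(_sample(od_to_gdw=0.462))
    y_46 = growth_yield(_sample(od_to_gdw=0.46))
    assert y_46 / y_462 == pytest.approx(0.46 / 0.462, rel=1e-12)


def test_yield_homogeneity():
    base = growth_yield(_sample())
    assert growth_yield(_sample(od660=0.6)) == pytest.approx(2 * base)
    assert growth_yield(_sample(dilution_rate=0.12)) == pytest.approx(2 * base)


# -- unit bridge ------------------------------------------------------------

def test_specific_flux_bridge():
    s = ChemostatSample(dilution_rate=0.06, od660=1.0, ch4_ml_min=22.4,
                        od_to_gdw=1.0, volume_l=1.0)
    assert ch4_specific_flux(s) == pytest.approx(60.0)


def test_specific_flux_scales_inversely_with_biomass():
    s1 = ChemostatSample(dilution_rate=0.06, od660=0.3, ch4_ml_min=2.0)
    s2 = ChemostatSample(dilution_rate=0.06, od660=0.6, ch4_ml_min=2.0)
    assert ch4_specific_flux(s1) == pytest.approx(2 * ch4_specific_flux(s2))


def test_invalid_samples_rejected():
    with pytest.raises(ValueError):
        ChemostatSample(dilution_rate=0.06, od660=0.0, ch4_ml_min=2.0)
    with pytest.raises(ValueError):
        ChemostatSample(dilution_rate=2.0, od660=0.3, ch4_ml_min=2.0)


# -- maintenance fitting -----------------------------------------------------

def test_noise_free_recovery_of_generating_parameters(core_model):
    spec = ChemostatGenSpec(gam=100.0, ngam=2.0, noise_sd_frac=0.0, seed=7)
    samples = generate_chemostat_samples(core_model, spec)
    fit = fit_maintenance(core_model, samples)
    assert fit.gam == pytest.approx(100.0, abs=1e-6)
    assert fit.ngam == pytest.approx(2.0, abs=1e-6)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-9)


def test_single_sample_is_an_error(core_model):
    spec = ChemostatGenSpec(noise_sd_frac=0.0, seed=0)
    samples = generate_chemostat_samples(core_model, spec)[:1]
    with pytest.raises(ValueError):
        fit_maintenance(core_model, samples)


def test_apply_then_refit_is_a_fixpoint(core_model):
    fit = MaintenanceFit(gam=169.9, ngam=5.0, r_squared=1.0, n_samples=9)
    trained = apply_maintenance(core_model, fit)
    assert trained.reactions["biomass[c0]"].stoich["atp[c0]"] == pytest.approx(-169.9)
    assert trained.reactions["rxn00062[c0]"].lower_bound == pytest.approx(5.0)
    spec = ChemostatGenSpec(gam=169.9, ngam=5.0, noise_sd_frac=0.0, seed=3)
    samples = generate_chemostat_samples(trained, spec)
    refit = fit_maintenance(trained, samples)
    assert refit.gam == pytest.approx(169.9, abs=1e-6)
    assert refit.ngam == pytest.approx(5.0, abs=1e-6)


def test_positive_ngam_forces_substrate_use_at_zero_growth(core_model):
    from methanofba import optimize, set_medium
    from methanofba.builder import medium_preset

    fit = MaintenanceFit(gam=169.9, ngam=5.0, r_squared=1.0, n_samples=9)
    trained = set_medium(apply_maintenance(core_model, fit),
                         medium_preset("H2_CO2"))
    bm = trained.reactions["biomass[c0]"]
    bm.lower_bound = bm.upper_bound = 0.0
    sol = optimize(trained, objective_id="rxn00062[c0]", maximize=False)
    assert sol.ok
    assert sol.fluxes["EX_h2[e0]"] < -1.0  # hydrogen burned for upkeep


# -- LOOCV -------------------------------------------------------------------

def test_loocv_noise_free_predictions_match_measurements(core_model):
    spec = ChemostatGenSpec(gam=169.9, ngam=5.0, noise_sd_frac=0.0,
                            n_samples=5, seed=11)
    samples = generate_chemostat_samples(core_model, spec)
    preds = loocv_yield_predictions(core_model, samples)
    for p in preds:
        assert p.predicted_yield == pytest.approx(p.measured_yield, rel=1e-5)
        assert p.within_ci


def test_loocv_requires_three_samples(core_model):
    spec = ChemostatGenSpec(noise_sd_frac=0.0, n_samples=2, seed=0)
    samples = generate_chemostat_samples(core_model, spec)
    with pytest.raises(ValueError):
        loocv_yield_predictions(core_model, samples)


def test_loocv_uses_supplied_confidence_intervals(core_model):
    spec = ChemostatGenSpec(gam=169.9, ngam=5.0, noise_sd_frac=0.0,
                            n_samples=3, seed=2)
    samples = generate_chemostat_samples(core_model, spec)
    from dataclasses import replace
    wide = [replace(s, ci_low=0.0, ci_high=100.0) for s in samples]
    preds = loocv_yield_predictions(core_model, wide)
    assert all(p.ci_low == 0.0 and p.ci_high == 100.0 for p in preds)
    assert all(p.within_ci for p in preds)
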