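"""Chemostat growth yields and ATP maintenance (GAM/NGAM) fitting.

At steady state in a chemostat the specific growth rate equals the
dilution rate D. Growth yield Y (gDCW per mol CH₄) is computed from
optical density, methane evolution and doubling time:

    t_d [min] = 60 · ln 2 / D[h⁻¹]
    Y = (OD₆₆₀ / CH₄[ml·min⁻¹]) · c · V · (1/t_d) · 22,400 ml·mol⁻¹

with c the OD₆₆₀ → dry-weight conversion (g·l⁻¹ per OD unit, measured
0.462; the historical formula constant 0.46 is available by configuration)
and V the culture volume in litres.

Maintenance fitting follows the Thiele–Palsson chemostat procedure: at
each sampling point the model is constrained to the measured growth rate
and methane secretion flux and ATP hydrolysis (rxn00062[c0]) is maximized
with the (untrained) biomass ATP requirement removed; ordinary
least-squares of the ATP optimum against growth rate gives the
growth-associated maintenance (slope, mmol ATP·gDCW⁻¹) and the
non-growth-associated maintenance (intercept, mmol ATP·gDCW⁻¹·h⁻¹).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import statsmodels.api as sm

from . import builder
from .fba import STATUS_OPTIMAL, optimize
from .network import MetabolicModel, set_medium

#: measured OD660 -> dry weight conversion, g/l per OD unit
OD_TO_GDW_DEFAULT = 0.462
#: ideal-gas molar volume used by the yield formula, ml/mol
ML_PER_MOL = 22400.0
#: medium preset used for maintenance fitting and yield prediction
FIT_MEDIUM = "H2_CO2"


@dataclass
class ChemostatSample:
    """One steady-state chemostat measurement.

    dilution_rate is h⁻¹ (equal to growth rate at steady state), od660 the
    measured optical density, ch4_ml_min the methane evolution in ml/min
    for the whole culture of ``volume_l`` litres. Optional ci_low/ci_high
    carry a replicate-derived 95% CI on the measured yield.
    """

    dilution_rate: float
    od660: float
    ch4_ml_min: float
    volume_l: float = 1.0
    od_to_gdw: float = OD_TO_GDW_DEFAULT
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.dilution_rate < 1.0:
            raise ValueError(f"dilution rate {self.dilution_rate} outside (0, 1) h-1")
        for field_name in ("od660", "ch4_ml_min", "volume_l", "od_to_gdw"):
            if getattr(self, field_name) <= 0:
                raise ValueError(f"{field_name} must be positive")

    @property
    def td_min(self) -> float:
        return doubling_time(self.dilution_rate)


@dataclass
class MaintenanceFit:
    """Fitted ATP maintenance: slope (GAM) and intercept (NGAM)."""

    gam: float
    ngam: float
    r_squared: float
    n_samples: int

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("maintenance fit needs at least 2 samples")
        if not (math.isfinite(self.gam) and math.isfinite(self.ngam)):
            raise ValueError("non-finite maintenance fit")


def doubling_time(dilution_rate: float) -> float:
    """Doubling time in minutes: 60·ln2 / D[h⁻¹]."""
    if dilution_rate <= 0:
        raise ValueError("dilution rate must be positive")
    return 60.0 * math.log(2.0) / dilution_rate


def growth_yield(sample: ChemostatSample) -> float:
    """Growth yield Y in gDCW per mol CH₄."""
    if sample.ch4_ml_min <= 0:
        raise ValueError("CH4 evolution must be positive")
    return (
        sample.od660 / sample.ch4_ml_min
        * sample.od_to_gdw * sample.volume_l
        * (1.0 / sample.td_min) * ML_PER_MOL
    )


def ch4_specific_flux(sample: ChemostatSample) -> float:
    """Biomass-specific methane secretion, mmol CH₄ · gDCW⁻¹ · h⁻¹.

    Unit bridge between culture-level readings and model exchange fluxes:
    (ml/min · 60 / 22.4 ml·mmol⁻¹) per gram dry weight in the vessel.
    """
    gdw = sample.od660 * sample.od_to_gdw * sample.volume_l
    if gdw <= 0:
        raise ValueError("non-positive biomass in sample")
    return sample.ch4_ml_min * 60.0 / (ML_PER_MOL / 1000.0) / gdw


def _constrained_atp_max(model: MetabolicModel, sample: ChemostatSample) -> float:
    """Max ATP hydrolysis with growth and CH4 secretion fixed to a sample."""
    work = model.copy()
    bm = work.reactions[builder.BIOMASS_ID]
    bm.lower_bound = bm.upper_bound = sample.dilution_rate
    ex = work.reactions[builder.CH4_EXCHANGE_ID]
    ex.lower_bound = ex.upper_bound = ch4_specific_flux(sample)
    maint = work.reactions[builder.MAINTENANCE_ID]
    maint.lower_bound, maint.upper_bound = 0.0, 1000.0
    sol = optimize(work, secondary="none", objective_id=builder.MAINTENANCE_ID)
    if sol.status != STATUS_OPTIMAL:
        raise RuntimeError(
            f"sample D={sample.dilution_rate}: ATP maximization {sol.status}"
        )
    return sol.objective_value


def fit_maintenance(
    model: MetabolicModel,
    samples: list[ChemostatSample],
    medium: str = FIT_MEDIUM,
) -> MaintenanceFit:
    """Fit GAM (slope) and NGAM (intercept) from chemostat samples.

    The biomass ATP coefficient is zeroed during the per-sample ATP
    maximization so the regression slope measures the total
    growth-associated ATP demand; apply_maintenance then writes the fitted
    values back into the model, making apply→refit a fixpoint.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 chemostat samples to fit maintenance")
    base = set_medium(model, builder.medium_preset(medium))
    base = builder.set_gam(base, 0.0, copy=False)
    atp = []
    for i, sample in enumerate(samples):
        try:
            atp.append(_constrained_atp_max(base, sample))
        except RuntimeError as exc:
            raise RuntimeError(f"sample {i}: {exc}") from exc
    growth = np.array([s.dilution_rate for s in samples])
    design = sm.add_constant(growth)
    fit = sm.OLS(np.array(atp), design).fit()
    return MaintenanceFit(
        gam=float(fit.params[1]),
        ngam=float(fit.params[0]),
        r_squared=float(fit.rsquared) if len(samples) > 2 else 1.0,
        n_samples=len(samples),
    )


def apply_maintenance(model: MetabolicModel, fit: MaintenanceFit) -> MetabolicModel:
    """Write fitted maintenance into a copy of the model: GAM becomes the
    biomass ATP coefficient, NGAM the lower bound of rxn00062[c0]."""
    out = builder.set_gam(model, max(fit.gam, 0.0))
    return builder.set_ngam(out, max(fit.ngam, 0.0), copy=False)


@dataclass
class YieldPrediction:
    sample: ChemostatSample
    measured_yield: float
    predicted_yield: float
    predicted_growth: float
    ci_low: float
    ci_high: float

    @property
    def within_ci(self) -> bool:
        return self.ci_low <= self.predicted_yield <= self.ci_high


def loocv_yield_predictions(
    model: MetabolicModel,
    samples: list[ChemostatSample],
    medium: str = FIT_MEDIUM,
    noise_sd_frac: float = 0.03,
) -> list[YieldPrediction]:
    """Leave-one-out cross-validated growth-yield predictions.

    For each held-out sample the maintenance is fitted on the remaining
    points and applied; the model's methane secretion is then constrained
    to the held-out measurement and maximum growth predicted, which the
    yield formula converts to a predicted Y. The 95% CI uses the sample's
    stored interval when present, otherwise the stated replicate reading
    noise on OD and CH₄ (Y relative sd = noise_sd_frac·√2).
    """
    if len(samples) < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    out = []
    for i, test in enumerate(samples):
        train = samples[:i] + samples[i + 1:]
        fit = fit_maintenance(model, train, medium=medium)
        trained = apply_maintenance(model, fit)
        trained = set_medium(trained, builder.medium_preset(medium))
        ex = trained.reactions[builder.CH4_EXCHANGE_ID]
        ex.lower_bound = ex.upper_bound = ch4_specific_flux(test)
        sol = optimize(trained, secondary="none")
        if sol.status != STATUS_OPTIMAL:
            raise RuntimeError(f"LOOCV test point {i}: prediction {sol.status}")
        mu = max(sol.objective_value, 1e-12)
        predicted = replace(test, dilution_rate=mu)
        y_meas = growth_yield(test)
        y_pred = growth_yield(predicted)
        if test.ci_low is not None and test.ci_high is not None:
            lo, hi = test.ci_low, test.ci_high
        else:
            half = 1.96 * noise_sd_frac * math.sqrt(2.0) * y_meas
            lo, hi = y_meas - half, y_meas + half
        out.append(YieldPrediction(test, y_meas, y_pred, mu, lo, hi))
    return out
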