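"""Synthetic inputs: chemostat samples with known maintenance truths, the
hydrogenase knockout validation panel, and random toy networks for the
brute-force FBA oracle.

The chemostat generator emulates steady-state continuous culture of
M. maripaludis under H₂ limitation at dilution rates 0.045–0.090 h⁻¹:
for each dilution rate the model (with the generating GAM/NGAM applied)
yields the stoichiometrically required methane secretion, which is
converted back to instrument readings (OD₆₆₀, ml CH₄/min) and perturbed
with multiplicative Gaussian reading noise — noise lives on the readings,
as it does on a spectrophotometer and a GC, not on derived yields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import builder
from .chemostat import (
    OD_TO_GDW_DEFAULT, ML_PER_MOL, ChemostatSample, MaintenanceFit,
    apply_maintenance,
)
from .fba import STATUS_OPTIMAL, optimize
from .knockouts import LETHAL, NONLETHAL, UNKNOWN, KnockoutCase
from .network import MetabolicModel, Metabolite, Reaction, set_medium


@dataclass
class ChemostatGenSpec:
    """Generating conditions for synthetic chemostat data.

    gam/ngam are the generating maintenance truths (mmol ATP·gDCW⁻¹ and
    mmol ATP·gDCW⁻¹·h⁻¹); n_samples dilution rates are evenly spaced over
    dilution_range (h⁻¹); noise_sd_frac is the fractional sd of the
    multiplicative reading noise on OD₆₆₀ and CH₄ (3% default).
    """

    gam: float = 169.9
    ngam: float = 5.0
    n_samples: int = 9
    dilution_range: tuple[float, float] = (0.045, 0.090)
    noise_sd_frac: float = 0.03
    seed: int = 0
    od660_nominal: float = 0.30
    volume_l: float = 1.0
    od_to_gdw: float = OD_TO_GDW_DEFAULT

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need n_samples >= 2")
        lo, hi = self.dilution_range
        if not (0 < lo <= hi):
            raise ValueError("dilution range must be positive and ordered")
        if self.noise_sd_frac < 0:
            raise ValueError("noise_sd_frac must be >= 0")


def generate_chemostat_samples(
    model: MetabolicModel,
    spec: ChemostatGenSpec,
    medium: str = "H2_CO2",
) -> list[ChemostatSample]:
    """Simulate steady-state chemostat samples at the generating truths.

    For each dilution rate D the growth flux is fixed to D and the methane
    exchange minimized (the stoichiometric requirement at that growth
    rate); the unit bridge then yields instrument readings at the nominal
    cell density, each multiplied by (1 + ε), ε ~ N(0, noise_sd_frac).
    Deterministic under seed.
    """
    rng = np.random.default_rng(spec.seed)
    fit = MaintenanceFit(gam=spec.gam, ngam=spec.ngam, r_squared=1.0, n_samples=2)
    work = apply_maintenance(model, fit)
    work = set_medium(work, builder.medium_preset(medium))
    gdw = spec.od660_nominal * spec.od_to_gdw * spec.volume_l
    samples = []
    for d_rate in np.linspace(*spec.dilution_range, spec.n_samples):
        point = work.copy()
        bm = point.reactions[builder.BIOMASS_ID]
        bm.lower_bound = bm.upper_bound = float(d_rate)
        sol = optimize(point, secondary="none",
                       objective_id=builder.CH4_EXCHANGE_ID, maximize=False)
        if sol.status != STATUS_OPTIMAL:
            raise RuntimeError(f"dilution rate {d_rate:.4f} h-1 infeasible: {sol.status}")
        v_ch4 = sol.objective_value  # mmol/gDCW/h
        ch4_ml_min = v_ch4 * gdw * (ML_PER_MOL / 1000.0) / 60.0
        eps_od, eps_ch4 = rng.normal(0.0, spec.noise_sd_frac, size=2)
        samples.append(ChemostatSample(
            dilution_rate=float(d_rate),
            od660=spec.od660_nominal * (1.0 + eps_od),
            ch4_ml_min=ch4_ml_min * (1.0 + eps_ch4),
            volume_l=spec.volume_l,
            od_to_gdw=spec.od_to_gdw,
        ))
    return samples


# ---------------------------------------------------------------------------
# knockout validation panel
# ---------------------------------------------------------------------------

#: hydrogenase-complex -> gene mapping of the core model
COMPLEX_GENES = {
    "Fru": "fruA", "Frc": "frcA", "Vhu": "vhuU", "Vhc": "vhcG",
    "Hmd": "hmdA", "Eha": "ehaA", "Ehb": "ehbA", "Fdh": "fdhA",
    "GAPOR": "gapor",
}

CONDITIONS = ("H2_CO2", "formate", "McNA", "acetate_only")

#: genotype label -> deleted complexes
GENOTYPES: dict[str, tuple[str, ...]] = {
    "WT": (),
    "Dfru": ("Fru",),
    "Dfrc": ("Frc",),
    "Dfru-frc": ("Fru", "Frc"),
    "Dhmd": ("Hmd",),
    "Dfru-hmd": ("Fru", "Hmd"),
    "Dfrc-hmd": ("Frc", "Hmd"),
    "Dfru-frc-hmd": ("Fru", "Frc", "Hmd"),
    "Dvhu": ("Vhu",),
    "Dvhc": ("Vhc",),
    "Dvhu-vhc": ("Vhu", "Vhc"),
    "Dehb": ("Ehb",),
    "Dfru-frc-ehb": ("Fru", "Frc", "Ehb"),
    "Dfdh": ("Fdh",),
    "D5H2ase": ("Fru", "Frc", "Vhu", "Vhc", "Hmd"),
    "D6H2ase": ("Fru", "Frc", "Vhu", "Vhc", "Hmd", "Ehb"),
    "D6H2ase_supp": ("Fru", "Frc", "Vhu", "Vhc", "Hmd", "Ehb"),
    "D7H2ase_sup": ("Fru", "Frc", "Vhu", "Vhc", "Hmd", "Ehb", "Eha"),
}

#: observed phenotypes of the 30 validated genotype × condition cells,
#: (label, condition) -> lethal/nonlethal
OBSERVED: dict[tuple[str, str], str] = {
    ("WT", "H2_CO2"): NONLETHAL,
    ("Dfru", "H2_CO2"): NONLETHAL,
    ("Dfrc", "H2_CO2"): NONLETHAL,
    ("Dfru-frc", "H2_CO2"): NONLETHAL,
    ("Dhmd", "H2_CO2"): NONLETHAL,
    ("Dfru-hmd", "H2_CO2"): NONLETHAL,
    ("Dfrc-hmd", "H2_CO2"): NONLETHAL,
    ("Dfru-frc-hmd", "H2_CO2"): LETHAL,
    ("Dvhu", "H2_CO2"): NONLETHAL,
    ("Dvhc", "H2_CO2"): NONLETHAL,
    ("Dvhu-vhc", "H2_CO2"): LETHAL,
    ("Dehb", "H2_CO2"): NONLETHAL,
    ("Dfru-frc-ehb", "H2_CO2"): NONLETHAL,
    ("Dfdh", "H2_CO2"): NONLETHAL,
    ("D5H2ase", "H2_CO2"): LETHAL,
    ("WT", "formate"): NONLETHAL,
    ("Dfru-frc", "formate"): NONLETHAL,
    ("Dhmd", "formate"): NONLETHAL,
    ("Dfru-frc-hmd", "formate"): NONLETHAL,
    ("Dvhu-vhc", "formate"): NONLETHAL,
    ("D5H2ase", "formate"): LETHAL,
    ("D6H2ase", "formate"): LETHAL,
    ("D6H2ase_supp", "formate"): NONLETHAL,
    ("D7H2ase_sup", "formate"): NONLETHAL,
    ("WT", "McNA"): NONLETHAL,
    ("Dfru-frc", "McNA"): NONLETHAL,
    ("Dhmd", "McNA"): NONLETHAL,
    ("Dfdh", "McNA"): NONLETHAL,
    ("Dehb", "McNA"): NONLETHAL,
    ("WT", "acetate_only"): LETHAL,
}

#: the GAPOR-overexpressing suppressor cases (gapor_mode = unbounded)
GAPOR_UNBOUNDED = {("D6H2ase_supp", "formate"), ("D7H2ase_sup", "formate")}


def generate_knockout_fixture() -> list[KnockoutCase]:
    """The hydrogenase knockout validation panel (synthetic transcription).

    A synthetic stand-in for the published validation grid, which is only
    available as a figure: 18 genotypes (hydrogenase complexes at complex
    granularity — no locus tags) × 4 growth conditions, with observed
    lethal/nonlethal phenotypes for the 30 experimentally characterised
    cells drawn from the M. maripaludis hydrogenase-mutant literature and
    constrained to the published summary statistics (28/30 correct, 93%
    accuracy, MCC 0.78, the two errors being the formate Δ5/Δ6-hydrogenase
    cases). The remaining 42 combinations are emitted with observed =
    "unknown" and are simulated but never scored. Exactly the two
    GAPOR-overexpressing suppressor cases carry gapor_mode="unbounded".
    """
    cases = []
    for label, complexes in GENOTYPES.items():
        genes = frozenset(COMPLEX_GENES[c] for c in complexes)
        for condition in CONDITIONS:
            key = (label, condition)
            cases.append(KnockoutCase(
                label=label,
                deleted_genes=genes,
                condition=condition,
                observed=OBSERVED.get(key, UNKNOWN),
                gapor_mode="unbounded" if key in GAPOR_UNBOUNDED else "zero",
            ))
    return cases


# ---------------------------------------------------------------------------
# random toy networks
# ---------------------------------------------------------------------------

def generate_toy_network(n_reactions: int, seed: int = 0) -> MetabolicModel:
    """Random connected, mass-balanced toy network for oracle testing.

    One substrate exchange, one product exchange, a conversion chain
    between them (all species share one abstract element so every internal
    reaction balances), optional parallel shortcut reactions, random
    finite bounds and random reversibility. Deterministic under seed.
    """
    if not 3 <= n_reactions <= 12:
        raise ValueError("toy networks support 3..12 reactions")
    rng = np.random.default_rng(seed)
    n_shortcuts = int(rng.integers(0, max(1, n_reactions - 4) + 1)) if n_reactions > 4 else 0
    n_chain = n_reactions - 2 - n_shortcuts  # internal conversions
    model = MetabolicModel(name=f"toy_{n_reactions}_{seed}")

    chain_mets = ["s[e0]"] + [f"m{i}[c0]" for i in range(n_chain - 1)] + ["p[e0]"]
    model.add_metabolite(Metabolite("s[e0]", "substrate", "X", 0, "e0"))
    model.add_metabolite(Metabolite("p[e0]", "product", "X", 0, "e0"))
    for mid in chain_mets[1:-1]:
        model.add_metabolite(Metabolite(mid, mid, "X", 0, "c0"))

    uptake = float(rng.uniform(1.0, 10.0))
    model.add_reaction(Reaction("EX_s[e0]", "substrate exchange", {"s[e0]": -1.0},
                                -uptake, 100.0, kind="exchange"))
    model.add_reaction(Reaction("EX_p[e0]", "product exchange", {"p[e0]": -1.0},
                                0.0, 100.0, kind="exchange"))
    for i in range(n_chain):
        cap = float(rng.uniform(uptake, 20.0))
        reversible = bool(rng.random() < 0.3)
        model.add_reaction(Reaction(
            f"R{i}[c0]", f"step {i}",
            {chain_mets[i]: -1.0, chain_mets[i + 1]: 1.0},
            -cap if reversible else 0.0, cap,
            kind="transport" if "[e0]" in chain_mets[i] + chain_mets[i + 1] else "internal",
        ))
    for k in range(n_shortcuts):
        i, j = sorted(rng.choice(len(chain_mets), size=2, replace=False))
        if i == j:
            continue
        cap = float(rng.uniform(0.5, 15.0))
        model.add_reaction(Reaction(
            f"S{k}[c0]", f"shortcut {k}",
            {chain_mets[i]: -1.0, chain_mets[j]: 1.0},
            0.0, cap,
            kind="transport" if "[e0]" in chain_mets[i] + chain_mets[j] else "internal",
        ))
    model.objective_id = "EX_p[e0]"
    model.validate()
    return model
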