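"""Exchange-flux overall free-energy accounting (the dG ledger).

The exchange reactions of a model jointly represent the organism's overall
biochemical conversion, so its overall free-energy rate can be estimated
from exchange fluxes alone: each exchange ``A[e0] ⇌`` is augmented to

    A[e0] ⇌ (ΔG_A) · dG

where dG is a bookkeeping pseudo-metabolite and ΔG_A the metabolite's
effective formation energy (kJ/mol). Mass balance is restored by letting
dG leave through its own drain exchange, GIBBS_kJ_GDW, whose flux at an
FBA optimum equals Σᵢ ΔG_eff(i) · v_EX(i) — the overall free-energy rate
in kJ·gDCW⁻¹·h⁻¹. Optionally that flux is constrained ≤ 0, imposing the
second law on the organism as a whole (a far lighter touch than
reaction-by-reaction thermodynamic constraints, which are out of scope).

Formation energies are inputs referenced to 1 mM, 25 °C, pH 7, I = 0.1 M;
deviating effective concentrations c (mM) shift them by RT·ln(c / 1 mM).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from . import builder
from .fba import FluxSolution, optimize
from .network import MetabolicModel, Metabolite, Reaction, set_medium

R_KJ = 8.314e-3  # kJ mol-1 K-1
DG_SPECIES_ID = "dG[e0]"
GIBBS_EXCHANGE_ID = "GIBBS_kJ_GDW"


@dataclass
class ThermoLedger:
    """Effective formation energies for exchanged metabolites.

    ``dgf`` maps extracellular metabolite id (e.g. "h2[e0]") to ΔGf°′ in
    kJ/mol at the 1 mM reference; ``concentrations`` maps metabolite id to
    effective concentration in mM (default 1 mM = reference, no shift).
    """

    dgf: dict[str, float] = field(default_factory=dict)
    concentrations: dict[str, float] = field(default_factory=dict)
    temperature: float = 298.15
    dg_species_id: str = DG_SPECIES_ID
    gibbs_exchange_id: str = GIBBS_EXCHANGE_ID

    def __post_init__(self) -> None:
        for mid, conc in self.concentrations.items():
            if conc <= 0:
                raise ValueError(f"non-positive concentration for {mid}")

    @classmethod
    def from_model(cls, model: MetabolicModel,
                   concentrations: dict[str, float] | None = None,
                   **kwargs) -> "ThermoLedger":
        """Collect the ΔGf values stored on the model's e0 metabolites."""
        dgf = {
            met.id: met.dgf_standard
            for met in model.metabolites.values()
            if met.compartment == "e0" and met.dgf_standard is not None
        }
        return cls(dgf=dgf, concentrations=dict(concentrations or {}), **kwargs)

    def effective_dgf(self, met_id: str) -> float:
        conc = self.concentrations.get(met_id, 1.0)
        return adjust_for_concentration(self.dgf[met_id], conc, self.temperature)


def adjust_for_concentration(dgf_standard: float, conc_mm: float,
                             temperature: float = 298.15) -> float:
    """ΔGf°′ + RT·ln(c / 1 mM); the 1 mM standard state means a
    concentration of 1 mM leaves the value unchanged."""
    if conc_mm <= 0:
        raise ValueError("concentration must be positive (mM)")
    return dgf_standard + R_KJ * temperature * math.log(conc_mm / 1.0)


def attach_free_energies(model: MetabolicModel, ledger: ThermoLedger | None = None
                         ) -> MetabolicModel:
    """Return a copy whose exchanges carry dG coefficients plus the
    GIBBS_kJ_GDW drain.

    Exchanges without a ledger entry get coefficient 0 with a warning
    (species whose group-contribution estimate is unreliable contribute
    nothing). With the drain unbounded all non-thermo optima are unchanged.
    Augmenting twice is an error.
    """
    if model.meta.get("thermo_attached"):
        raise ValueError("model already carries the free-energy ledger")
    out = model.copy()
    if ledger is None:
        ledger = ThermoLedger.from_model(out)
    out.add_metabolite(Metabolite(
        ledger.dg_species_id, "Free-energy ledger pseudo-metabolite",
        "", 0, "e0", is_pseudo=True,
    ))
    missing = []
    for rxn in out.exchanges():
        met_id = next(m for m in rxn.stoich if not out.metabolites[m].is_pseudo)
        if met_id in ledger.dgf:
            rxn.stoich[ledger.dg_species_id] = ledger.effective_dgf(met_id)
        else:
            rxn.stoich[ledger.dg_species_id] = 0.0
            missing.append(met_id)
    if missing:
        warnings.warn(
            "no formation energy for exchanged metabolites (coefficient 0): "
            + ", ".join(sorted(missing))
        )
    out.add_reaction(Reaction(
        ledger.gibbs_exchange_id, "Overall free-energy drain (kJ/gDCW/h)",
        {ledger.dg_species_id: -1.0}, -1e7, 1e7, kind="pseudo",
    ))
    out.meta["thermo_attached"] = True
    out.meta["thermo_ledger"] = ledger
    return out


def _refresh_coefficients(model: MetabolicModel, ledger: ThermoLedger) -> None:
    for rxn in model.exchanges():
        met_id = next(m for m in rxn.stoich
                      if not model.metabolites[m].is_pseudo)
        if met_id in ledger.dgf:
            rxn.stoich[ledger.dg_species_id] = ledger.effective_dgf(met_id)


def optimize_with_thermo(
    model: MetabolicModel,
    medium=None,
    concentrations: dict[str, float] | None = None,
    constrain_negative: bool = False,
    secondary: str = "l1",
) -> FluxSolution:
    """FBA on an augmented model, reporting the overall free-energy rate.

    ``concentrations`` (mM, keyed by extracellular metabolite id) update
    the effective formation energies before solving; ``constrain_negative``
    bounds the GIBBS drain flux ≤ 0, i.e. imposes the second law.
    """
    if not model.meta.get("thermo_attached"):
        raise ValueError("attach_free_energies must be applied first")
    ledger: ThermoLedger = model.meta["thermo_ledger"]
    work = model.copy()
    if medium is not None:
        if isinstance(medium, str):
            medium = builder.medium_preset(medium)
        work = set_medium(work, medium)
    if concentrations:
        merged = dict(ledger.concentrations)
        merged.update(concentrations)
        ledger = ThermoLedger(dict(ledger.dgf), merged, ledger.temperature,
                              ledger.dg_species_id, ledger.gibbs_exchange_id)
        _refresh_coefficients(work, ledger)
    drain = work.reactions[ledger.gibbs_exchange_id]
    if constrain_negative:
        drain.upper_bound = 0.0
    sol = optimize(work, secondary=secondary)
    if sol.ok:
        sol.total_free_energy = sol.fluxes[ledger.gibbs_exchange_id]
    return sol


def free_energy_oracle(model: MetabolicModel, solution: FluxSolution,
                       concentrations: dict[str, float] | None = None) -> float:
    """Independent dot product Σ ΔGf_eff(i) × v_EX(i) over all exchanges,
    recomputed from the ledger values — must equal the GIBBS drain flux."""
    ledger: ThermoLedger = model.meta["thermo_ledger"]
    if concentrations:
        merged = dict(ledger.concentrations)
        merged.update(concentrations)
        ledger = ThermoLedger(dict(ledger.dgf), merged, ledger.temperature,
                              ledger.dg_species_id, ledger.gibbs_exchange_id)
    total = 0.0
    for rxn in model.exchanges():
        met_id = next(m for m in rxn.stoich
                      if not model.metabolites[m].is_pseudo)
        if met_id in ledger.dgf:
            total += ledger.effective_dgf(met_id) * solution.fluxes.get(rxn.id, 0.0)
    return total


def h2_sweep(model: MetabolicModel, h2_concentrations,
             medium=None, constrain_negative: bool = False):
    """Overall free energy and growth across H₂ levels (mM).

    Returns a pandas DataFrame with one row per concentration, sorted by
    concentration: columns h2_mM, total_free_energy, growth, status.
    """
    import pandas as pd

    rows = []
    for conc in sorted(h2_concentrations):
        sol = optimize_with_thermo(
            model, medium=medium, concentrations={"h2[e0]": float(conc)},
            constrain_negative=constrain_negative,
        )
        rows.append({
            "h2_mM": float(conc),
            "total_free_energy": sol.total_free_energy if sol.ok else float("nan"),
            "growth": sol.objective_value if sol.ok else float("nan"),
            "status": sol.status,
        })
    return pd.DataFrame(rows, columns=["h2_mM", "total_free_energy", "growth", "status"])
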