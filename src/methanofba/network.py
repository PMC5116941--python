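"""Domain types for constraint-based metabolic models.

Conventions follow the Model SEED / COBRA style used for archaeal
reconstructions: compartment tags ``[c0]`` (cytosol) and ``[e0]``
(extracellular), exchange reactions named ``EX_{metabolite id}[e0]`` whose
positive flux is secretion and negative flux is uptake, and all fluxes in
mmol · gDCW⁻¹ · h⁻¹.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from .gpr import GPRExpression

COMPARTMENTS = ("c0", "e0")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula string into element counts.

    Carrier scaffolds may use abstract element symbols (e.g. ``Fd`` for the
    ferredoxin core); only internal consistency matters for balancing.
    """
    if formula is None:
        raise ValueError("missing formula")
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"unparseable formula {formula!r}")
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        pos = m.end()
    if pos != len(formula):
        raise ValueError(f"unparseable formula {formula!r}")
    if any(v < 0 for v in counts.values()):
        raise ValueError(f"negative element count in {formula!r}")
    return counts


@dataclass
class Metabolite:
    """A chemical species in one compartment.

    ``dgf_standard`` is the transformed standard free energy of formation
    (kJ/mol at 1 mM, 25 °C, pH 7, I = 0.1 M), carried only for exchanged
    species used by the thermodynamic ledger. ``is_pseudo`` marks
    bookkeeping species (the dG ledger metabolite, biomass) exempt from
    elemental balance.
    """

    id: str
    name: str = ""
    formula: str = ""
    charge: int = 0
    compartment: str = "c0"
    dgf_standard: float | None = None
    is_pseudo: bool = False

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if not self.id.endswith(f"[{self.compartment}]"):
            raise ValueError(
                f"metabolite id {self.id!r} does not match compartment {self.compartment!r}"
            )
        if not self.is_pseudo:
            parse_formula(self.formula)

    @property
    def base_id(self) -> str:
        """Metabolite id without the compartment suffix."""
        return self.id[: self.id.rindex("[")]

    def element_counts(self) -> dict[str, int]:
        return {} if self.is_pseudo else parse_formula(self.formula)


REACTION_KINDS = ("internal", "transport", "exchange", "pseudo")


@dataclass
class Reaction:
    """A stoichiometric reaction with flux bounds and an optional GPR.

    ``stoich`` maps metabolite id to coefficient (negative = consumed).
    Bounds are mmol · gDCW⁻¹ · h⁻¹; a reaction is reversible iff its lower
    bound is negative.
    """

    id: str
    name: str = ""
    stoich: dict[str, float] = field(default_factory=dict)
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    gpr: GPRExpression | None = None
    subsystem: str = ""
    kind: str = "internal"
    likelihood: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in REACTION_KINDS:
            raise ValueError(f"unknown reaction kind {self.kind!r}")
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id}: lower bound {self.lower_bound} > upper bound {self.upper_bound}"
            )
        if self.likelihood is not None and not (0.0 <= self.likelihood <= 1.0):
            raise ValueError(f"reaction {self.id}: likelihood outside [0,1]")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def gene_set(self) -> set[str]:
        return self.gpr.genes() if self.gpr is not None else set()


@dataclass
class Coupling:
    """Linear inequality over fluxes: Σ aᵢ·|vᵢ| + Σ bⱼ·vⱼ ≤ ub.

    Absolute-value terms are expressed through split non-negative flux
    variables inside the LP, keeping the problem linear.
    """

    abs_terms: dict[str, float] = field(default_factory=dict)
    lin_terms: dict[str, float] = field(default_factory=dict)
    ub: float = 0.0
    name: str = ""

    def residual(self, fluxes: Mapping[str, float]) -> float:
        tot = sum(a * abs(fluxes.get(r, 0.0)) for r, a in self.abs_terms.items())
        tot += sum(b * fluxes.get(r, 0.0) for r, b in self.lin_terms.items())
        return tot - self.ub


class MetabolicModel:
    """Metabolites, reactions, genes and an objective: the Sv = 0 system.

    The stoichiometric matrix S (one row per metabolite, one column per
    reaction, columns ordered by sorted reaction id) is derived on demand.
    """

    def __init__(
        self,
        metabolites: Iterable[Metabolite] = (),
        reactions: Iterable[Reaction] = (),
        objective_id: str | None = None,
        couplings: Iterable[Coupling] = (),
        name: str = "",
        meta: dict | None = None,
    ) -> None:
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        self.couplings: list[Coupling] = list(couplings)
        self.name = name
        self.meta: dict = dict(meta or {})
        for met in metabolites:
            self.add_metabolite(met)
        for rxn in reactions:
            self.add_reaction(rxn)
        self.objective_id = objective_id

    # -- construction -----------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ValueError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ValueError(f"duplicate reaction id {rxn.id!r}")
        for mid in rxn.stoich:
            if mid not in self.metabolites:
                raise ValueError(f"reaction {rxn.id!r} references unknown metabolite {mid!r}")
        self.reactions[rxn.id] = rxn

    # -- derived views ----------------------------------------------------
    @property
    def genes(self) -> list[str]:
        out: set[str] = set()
        for rxn in self.reactions.values():
            out |= rxn.gene_set()
        return sorted(out)

    def reaction_ids(self) -> list[str]:
        return sorted(self.reactions)

    def metabolite_ids(self) -> list[str]:
        return sorted(self.metabolites)

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Return (S, metabolite ids, reaction ids) with sorted id ordering."""
        mids = self.metabolite_ids()
        rids = self.reaction_ids()
        mindex = {m: i for i, m in enumerate(mids)}
        S = np.zeros((len(mids), len(rids)))
        for j, rid in enumerate(rids):
            for mid, coeff in self.reactions[rid].stoich.items():
                S[mindex[mid], j] = coeff
        return S, mids, rids

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.kind == "exchange"]

    def copy(self) -> "MetabolicModel":
        model = MetabolicModel(name=self.name, meta=dict(self.meta))
        for met in self.metabolites.values():
            model.add_metabolite(replace(met))
        for rxn in self.reactions.values():
            model.add_reaction(
                replace(rxn, stoich=dict(rxn.stoich))
            )
        model.couplings = [
            Coupling(dict(c.abs_terms), dict(c.lin_terms), c.ub, c.name)
            for c in self.couplings
        ]
        model.objective_id = self.objective_id
        return model

    def validate(self) -> None:
        """Check structural invariants (ids, objective, exchange shape)."""
        if self.objective_id is not None and self.objective_id not in self.reactions:
            raise ValueError(f"objective {self.objective_id!r} is not a reaction")
        for rxn in self.reactions.values():
            if rxn.kind == "exchange":
                real = [m for m in rxn.stoich if not self.metabolites[m].is_pseudo]
                if len(real) != 1:
                    raise ValueError(f"exchange {rxn.id} must touch exactly one real metabolite")
                met = self.metabolites[real[0]]
                if met.compartment != "e0":
                    raise ValueError(f"exchange {rxn.id} metabolite must live in e0")
                expected = f"EX_{met.base_id}[e0]"
                if rxn.id != expected:
                    raise ValueError(f"exchange {rxn.id} should be named {expected}")
        for coupling in self.couplings:
            for rid in list(coupling.abs_terms) + list(coupling.lin_terms):
                if rid not in self.reactions:
                    raise ValueError(f"coupling references unknown reaction {rid!r}")


# -- medium handling -------------------------------------------------------

@dataclass
class MediumSpec:
    """Maximum uptake rates (mmol·gDCW⁻¹·h⁻¹) keyed by exchange reaction id."""

    uptake: dict[str, float] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        for rid, rate in self.uptake.items():
            if rate < 0:
                raise ValueError(f"negative uptake rate for {rid}")


def set_medium(model: MetabolicModel, medium: MediumSpec) -> MetabolicModel:
    """Return a copy with exchange lower bounds set to −rate for listed
    species and 0 otherwise; secretion stays unbounded (+1000)."""
    out = model.copy()
    exchange_ids = {r.id for r in out.exchanges()}
    for rid in medium.uptake:
        if rid not in exchange_ids:
            raise ValueError(f"medium lists unknown exchange reaction {rid!r}")
    for rid in exchange_ids:
        rxn = out.reactions[rid]
        rxn.lower_bound = -float(medium.uptake.get(rid, 0.0))
        rxn.upper_bound = 1000.0
    out.meta["medium"] = medium.name or "custom"
    return out


# -- mass/charge balance ----------------------------------------------------

@dataclass
class BalanceViolation:
    reaction_id: str
    element_residuals: dict[str, float]
    charge_residual: float


def check_mass_charge_balance(
    model: MetabolicModel, tol: float = 1e-9
) -> list[BalanceViolation]:
    """List non-exempt reactions with nonzero element or charge residual.

    Exchange and pseudo reactions (biomass, maintenance, ledger drains) are
    exempt: exchanges are single-sided by definition, pseudo reactions lump
    unmodelled chemistry.
    """
    violations = []
    for rid in model.reaction_ids():
        rxn = model.reactions[rid]
        if rxn.kind in ("exchange", "pseudo"):
            continue
        if any(model.metabolites[m].is_pseudo for m in rxn.stoich):
            continue
        elements: dict[str, float] = {}
        charge = 0.0
        for mid, coeff in rxn.stoich.items():
            met = model.metabolites[mid]
            for el, n in met.element_counts().items():
                elements[el] = elements.get(el, 0.0) + coeff * n
            charge += coeff * met.charge
        residuals = {el: v for el, v in elements.items() if abs(v) > tol}
        if residuals or abs(charge) > tol:
            violations.append(BalanceViolation(rid, residuals, charge))
    return violations


# -- dead-end detection ------------------------------------------------------

def find_dead_ends(model: MetabolicModel) -> tuple[list[str], list[str]]:
    """Structurally blocked metabolites and reactions.

    A metabolite is a dead end if, over all reactions still considered
    active, it can only be produced or only consumed (reversible reactions
    count for both directions; exchanges make their metabolite both
    producible and consumable). Reactions touching a dead end cannot carry
    steady-state flux; removal is iterated to a fixpoint so upstream chains
    are pruned too.
    """
    active = set(model.reactions)
    dead_mets: set[str] = set()
    while True:
        producible: set[str] = set()
        consumable: set[str] = set()
        touch_count: dict[str, int] = {}
        for rid in active:
            for mid in model.reactions[rid].stoich:
                touch_count[mid] = touch_count.get(mid, 0) + 1
        for rid in active:
            rxn = model.reactions[rid]
            fwd = rxn.upper_bound > 0
            rev = rxn.lower_bound < 0
            for mid, coeff in rxn.stoich.items():
                if coeff > 0:
                    if fwd:
                        producible.add(mid)
                    if rev:
                        consumable.add(mid)
                elif coeff < 0:
                    if fwd:
                        consumable.add(mid)
                    if rev:
                        producible.add(mid)
        newly_dead = {
            mid
            for mid in model.metabolites
            if mid not in dead_mets
            and touch_count.get(mid, 0) > 0
            # only produced, only consumed, or balanced by a single reaction
            # (which then cannot carry flux at steady state either way)
            and (not (mid in producible and mid in consumable)
                 or touch_count[mid] == 1)
        }
        if not newly_dead:
            break
        dead_mets |= newly_dead
        active = {
            rid
            for rid in active
            if not (set(model.reactions[rid].stoich) & dead_mets)
        }
    orphan = {
        mid
        for mid in model.metabolites
        if not any(mid in model.reactions[r].stoich for r in model.reactions)
    }
    dead_reactions = sorted(set(model.reactions) - active)
    return sorted(dead_mets | orphan), dead_reactions
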