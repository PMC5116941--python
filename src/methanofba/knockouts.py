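"""Gene-knockout phenotype simulation and scoring.

Knocking out a gene closes every reaction whose GPR rule evaluates false
without it. A genotype × growth-condition panel is simulated by FBA and
each case classified lethal/nonlethal against a threshold fraction
(default 10%) of condition-specific wild-type growth; predictions are
scored against observations with the Matthews correlation coefficient
(MCC), taking nonlethal (growth) as the positive class:

    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with MCC defined as 0 when the denominator vanishes.

GAPOR handling mirrors the original simulation scripts: the reaction is
constrained to zero flux in every case except genotypes marked as
GAPOR-overexpressing suppressors (gapor_mode="unbounded").
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from . import builder
from .fba import STATUS_OPTIMAL, optimize
from .gpr import GPRExpression
from .network import MetabolicModel, set_medium

LETHAL = "lethal"
NONLETHAL = "nonlethal"
UNKNOWN = "unknown"

#: growth below this absolute rate (1/h) counts as no growth even when the
#: wild type itself cannot grow on the condition (threshold x 0 = 0).
GROWTH_EPS = 1e-9


@dataclass(frozen=True)
class KnockoutCase:
    """One genotype × condition cell of the validation panel."""

    label: str
    deleted_genes: frozenset[str]
    condition: str
    observed: str = UNKNOWN
    gapor_mode: str = "zero"

    def __post_init__(self) -> None:
        if self.observed not in (LETHAL, NONLETHAL, UNKNOWN):
            raise ValueError(f"bad observed phenotype {self.observed!r}")
        if self.gapor_mode not in ("zero", "unbounded"):
            raise ValueError(f"bad gapor_mode {self.gapor_mode!r}")
        object.__setattr__(self, "deleted_genes", frozenset(self.deleted_genes))


@dataclass
class PanelPrediction:
    case: KnockoutCase
    growth: float
    wild_type_growth: float
    predicted: str

    @property
    def correct(self) -> bool | None:
        if self.case.observed == UNKNOWN:
            return None
        return self.predicted == self.case.observed


@dataclass
class ConfusionCounts:
    """Positive class = nonlethal (growth)."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else 0.0

    @property
    def mcc(self) -> float:
        num = self.tp * self.tn - self.fp * self.fn
        den = math.sqrt(
            float(self.tp + self.fp) * (self.tp + self.fn)
            * (self.tn + self.fp) * (self.tn + self.fn)
        )
        return num / den if den > 0 else 0.0


def evaluate_gpr(expr: GPRExpression | None, deleted: set[str],
                 known_genes: set[str] | None = None) -> bool:
    """Evaluate a GPR tree with the deleted genes set to False.

    An empty GPR (None) is always active. Deleted genes absent from
    ``known_genes`` are ignored with a warning.
    """
    if known_genes is not None:
        unknown = set(deleted) - known_genes
        if unknown:
            warnings.warn(f"ignoring unknown genes in deletion set: {sorted(unknown)}")
            deleted = set(deleted) & known_genes
    if expr is None:
        return True
    return expr.evaluate(set(deleted))


def delete_genes(model: MetabolicModel, genes) -> MetabolicModel:
    """Return a copy in which every reaction whose GPR evaluates inactive
    under the deletion is closed (bounds 0, 0); other reactions untouched."""
    deleted = set(genes)
    known = set(model.genes)
    out = model.copy()
    for rxn in out.reactions.values():
        if rxn.gpr is not None and not evaluate_gpr(rxn.gpr, deleted, known):
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return out


def _set_gapor(model: MetabolicModel, mode: str) -> None:
    rxn = model.reactions.get(builder.GAPOR_ID)
    if rxn is None:
        return
    if mode == "zero":
        rxn.lower_bound = rxn.upper_bound = 0.0
    else:
        rxn.lower_bound, rxn.upper_bound = 0.0, 1000.0


def simulate_panel(
    model: MetabolicModel,
    cases: list[KnockoutCase],
    threshold: float = 0.10,
) -> list[PanelPrediction]:
    """Simulate every knockout case and classify lethality.

    Wild-type growth is computed once per condition (GAPOR constrained to
    zero, like the non-suppressor cases). A case is predicted lethal iff
    its optimal growth is strictly below max(threshold × wild-type growth,
    1e-9); the epsilon covers conditions whose wild type cannot grow, where
    every genotype is then lethal. A wild type whose LP is infeasible
    (rather than optimal at zero growth) is an error.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    wild_type: dict[str, float] = {}
    for condition in sorted({c.condition for c in cases}):
        cond_model = set_medium(model, builder.medium_preset(condition))
        _set_gapor(cond_model, "zero")
        sol = optimize(cond_model)
        if sol.status != STATUS_OPTIMAL:
            raise RuntimeError(
                f"wild-type FBA on condition {condition!r} is {sol.status}"
            )
        wild_type[condition] = sol.objective_value

    predictions = []
    for case in cases:
        cond_model = set_medium(model, builder.medium_preset(case.condition))
        _set_gapor(cond_model, case.gapor_mode)
        ko = delete_genes(cond_model, case.deleted_genes)
        sol = optimize(ko)
        growth = sol.objective_value if sol.status == STATUS_OPTIMAL else 0.0
        wt = wild_type[case.condition]
        cutoff = max(threshold * wt, GROWTH_EPS)
        predicted = LETHAL if growth < cutoff else NONLETHAL
        predictions.append(PanelPrediction(case, growth, wt, predicted))
    return predictions


def confusion_and_mcc(predictions: list[PanelPrediction]) -> ConfusionCounts:
    """Confusion counts over cases with a known observed phenotype."""
    counts = ConfusionCounts()
    scored = 0
    for pred in predictions:
        obs = pred.case.observed
        if obs == UNKNOWN:
            continue
        scored += 1
        if obs == NONLETHAL and pred.predicted == NONLETHAL:
            counts.tp += 1
        elif obs == LETHAL and pred.predicted == LETHAL:
            counts.tn += 1
        elif obs == LETHAL and pred.predicted == NONLETHAL:
            counts.fp += 1
        else:
            counts.fn += 1
    if scored == 0:
        raise ValueError("no cases with an observed phenotype to score")
    return counts


def format_panel(predictions: list[PanelPrediction]) -> str:
    lines = [f"{'genotype':20s} {'condition':13s} {'growth':>10s} "
             f"{'predicted':>10s} {'observed':>10s}"]
    for p in predictions:
        lines.append(
            f"{p.case.label:20s} {p.case.condition:13s} {p.growth:10.5f} "
            f"{p.predicted:>10s} {p.case.observed:>10s}"
        )
    return "\n".join(lines)
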