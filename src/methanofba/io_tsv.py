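"""TSV model tables: a reactions sheet and a metabolites sheet.

Layout mirrors the comprehensive reaction/metabolite listing that
genome-scale reconstructions ship as supplementary tables:

reactions sheet   id, name, equation, lb, ub, gpr, subsystem, kind,
                  likelihood, objective
metabolites sheet id, name, formula, charge, compartment, dGf, is_pseudo

``path`` is a base path: ``write_model_tsv(model, "core")`` writes
``core_reactions.tsv`` and ``core_metabolites.tsv`` (plus
``core_couplings.tsv`` when flux couplings exist). The round trip is
lossless for every field.
"""

from __future__ import annotations

import math
import os
import re

import pandas as pd

from .gpr import parse_gpr
from .network import Coupling, MetabolicModel, Metabolite, Reaction

_ARROW = re.compile(r"\s*(<=>|=>|<=)\s*")


def _base(path: str) -> str:
    return path[:-4] if str(path).endswith(".tsv") else str(path)


def format_equation(rxn: Reaction) -> str:
    """``2 a[c0] + b[c0] <=> c[c0]``; exchanges render one-sided."""
    def side(items):
        parts = []
        for mid, coeff in sorted(items):
            parts.append(mid if coeff == 1 else f"{coeff:g} {mid}")
        return " + ".join(parts)

    lhs = [(m, -c) for m, c in rxn.stoich.items() if c < 0]
    rhs = [(m, c) for m, c in rxn.stoich.items() if c > 0]
    arrow = "<=>" if rxn.lower_bound < 0 else "=>"
    return f"{side(lhs)} {arrow} {side(rhs)}".strip()


def parse_equation(text: str) -> dict[str, float]:
    m = _ARROW.search(text)
    if not m:
        raise ValueError(f"no reaction arrow in equation {text!r}")
    lhs, rhs = text[: m.start()], text[m.end():]
    stoich: dict[str, float] = {}
    for side, sign in ((lhs, -1.0), (rhs, 1.0)):
        side = side.strip()
        if not side:
            continue
        for term in side.split(" + "):
            term = term.strip()
            if not term:
                continue
            bits = term.split(None, 1)
            if len(bits) == 2 and re.fullmatch(r"[-+0-9.eE]+", bits[0]):
                coeff, mid = float(bits[0]), bits[1]
            else:
                coeff, mid = 1.0, term
            stoich[mid] = stoich.get(mid, 0.0) + sign * coeff
    return stoich


def write_model_tsv(model: MetabolicModel, path: str) -> None:
    base = _base(path)
    mets = pd.DataFrame(
        [{
            "id": m.id, "name": m.name, "formula": m.formula,
            "charge": m.charge, "compartment": m.compartment,
            "dGf": m.dgf_standard if m.dgf_standard is not None else "",
            "is_pseudo": int(m.is_pseudo),
        } for m in (model.metabolites[i] for i in model.metabolite_ids())]
    )
    rxns = pd.DataFrame(
        [{
            "id": r.id, "name": r.name, "equation": format_equation(r),
            "lb": r.lower_bound, "ub": r.upper_bound,
            "gpr": r.gpr.to_string() if r.gpr is not None else "",
            "subsystem": r.subsystem, "kind": r.kind,
            "likelihood": r.likelihood if r.likelihood is not None else "",
            "objective": int(r.id == model.objective_id),
        } for r in (model.reactions[i] for i in model.reaction_ids())]
    )
    mets.to_csv(f"{base}_metabolites.tsv", sep="\t", index=False,
                float_format="%.17g")
    rxns.to_csv(f"{base}_reactions.tsv", sep="\t", index=False,
                float_format="%.17g")
    coup_path = f"{base}_couplings.tsv"
    if model.couplings:
        pd.DataFrame(
            [{
                "name": c.name,
                "abs_terms": ";".join(f"{k}:{v:g}" for k, v in sorted(c.abs_terms.items())),
                "lin_terms": ";".join(f"{k}:{v:g}" for k, v in sorted(c.lin_terms.items())),
                "ub": c.ub,
            } for c in model.couplings]
        ).to_csv(coup_path, sep="\t", index=False)
    elif os.path.exists(coup_path):
        os.remove(coup_path)


def _opt_float(value) -> float | None:
    if value is None or value == "" or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def read_model_tsv(path: str) -> MetabolicModel:
    base = _base(path)
    mets = pd.read_csv(f"{base}_metabolites.tsv", sep="\t",
                       keep_default_na=False, na_values=[],
                       float_precision="round_trip")
    rxns = pd.read_csv(f"{base}_reactions.tsv", sep="\t",
                       keep_default_na=False, na_values=[],
                       float_precision="round_trip")
    model = MetabolicModel(name=os.path.basename(base))
    for i, row in mets.iterrows():
        try:
            model.add_metabolite(Metabolite(
                id=str(row["id"]), name=str(row["name"]),
                formula=str(row["formula"]), charge=int(row["charge"]),
                compartment=str(row["compartment"]),
                dgf_standard=_opt_float(row["dGf"]),
                is_pseudo=bool(int(row["is_pseudo"])),
            ))
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{base}_metabolites.tsv line {i + 2}: {exc}") from exc
    objective = None
    for i, row in rxns.iterrows():
        try:
            rxn = Reaction(
                id=str(row["id"]), name=str(row["name"]),
                stoich=parse_equation(str(row["equation"])),
                lower_bound=float(row["lb"]), upper_bound=float(row["ub"]),
                gpr=parse_gpr(str(row["gpr"])) if str(row["gpr"]).strip() else None,
                subsystem=str(row["subsystem"]), kind=str(row["kind"]),
                likelihood=_opt_float(row["likelihood"]),
            )
            model.add_reaction(rxn)
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{base}_reactions.tsv line {i + 2}: {exc}") from exc
        if int(row["objective"]):
            objective = rxn.id
    model.objective_id = objective
    coup_path = f"{base}_couplings.tsv"
    if os.path.exists(coup_path):
        coups = pd.read_csv(coup_path, sep="\t", keep_default_na=False, na_values=[])
        for _, row in coups.iterrows():
            def terms(cell):
                out = {}
                for item in str(cell).split(";"):
                    if item:
                        k, v = item.rsplit(":", 1)
                        out[k] = float(v)
                return out
            model.couplings.append(Coupling(
                terms(row["abs_terms"]), terms(row["lin_terms"]),
                float(row["ub"]), str(row["name"]),
            ))
    model.validate()
    return model
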