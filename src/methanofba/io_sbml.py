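"""SBML level-2 input/output (legacy COBRA dialect).

Models are written as SBML level 2 version 4: species and reactions with
stoichiometry; flux bounds and the objective as the kinetic-law parameters
LOWER_BOUND / UPPER_BOUND / OBJECTIVE_COEFFICIENT; GPR strings, subsystem,
reaction kind, likelihood and metabolite formula/charge/ΔGf in XHTML notes
— the dialect constraint-based toolboxes used before the fbc package, so
the files load in other COBRA implementations.

Because square brackets are not legal in SBML identifiers, native ids such
as ``h2[c0]`` map to ``M_h2__c0`` / ``R_EX_h2__e0`` and back; the round
trip preserves the stoichiometric matrix, bounds, objective and couplings
(the last as a model-level note). Unsupported constructs in foreign files
raise errors rather than being silently dropped.
"""

from __future__ import annotations

import re

import libsbml

from .gpr import parse_gpr
from .network import Coupling, MetabolicModel, Metabolite, Reaction

_SBML_SUFFIX = re.compile(r"__([ce]0)$")


def _to_sbml_id(native: str, prefix: str) -> str:
    return prefix + native.replace("[", "__").replace("]", "")


def _from_sbml_id(sbml_id: str, prefix: str) -> str:
    s = sbml_id[len(prefix):] if sbml_id.startswith(prefix) else sbml_id
    return _SBML_SUFFIX.sub(r"[\1]", s)


def _notes(pairs: dict[str, str]) -> str:
    body = "".join(f"<p>{k}: {v}</p>" for k, v in pairs.items() if v != "")
    return f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>'


def _parse_notes(node) -> dict[str, str]:
    if node is None or not node.isSetNotes():
        return {}
    text = node.getNotesString()
    return dict(re.findall(r"<p>\s*([A-Z_0-9]+):\s*(.*?)\s*</p>", text, re.S))


def write_sbml(model: MetabolicModel, path: str) -> None:
    doc = libsbml.SBMLDocument(2, 4)
    sbml_model = doc.createModel()
    sbml_model.setId(re.sub(r"\W", "_", model.name or "model"))
    for comp_id in ("c0", "e0"):
        comp = sbml_model.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)

    for mid in model.metabolite_ids():
        met = model.metabolites[mid]
        sp = sbml_model.createSpecies()
        sp.setId(_to_sbml_id(mid, "M_"))
        sp.setName(met.name or mid)
        sp.setCompartment(met.compartment)
        sp.setInitialConcentration(0.0)
        sp.setBoundaryCondition(False)
        notes = {"FORMULA": met.formula, "CHARGE": str(met.charge)}
        if met.dgf_standard is not None:
            notes["DGF"] = repr(met.dgf_standard)
        if met.is_pseudo:
            notes["PSEUDO"] = "1"
        sp.setNotes(_notes(notes))

    for rid in model.reaction_ids():
        rxn = model.reactions[rid]
        sr = sbml_model.createReaction()
        sr.setId(_to_sbml_id(rid, "R_"))
        sr.setName(rxn.name or rid)
        sr.setReversible(rxn.lower_bound < 0)
        for mid, coeff in sorted(rxn.stoich.items()):
            ref = sr.createReactant() if coeff < 0 else sr.createProduct()
            ref.setSpecies(_to_sbml_id(mid, "M_"))
            ref.setStoichiometry(abs(coeff))
        law = sr.createKineticLaw()
        law.setFormula("FLUX_VALUE")
        for pname, value in (
            ("LOWER_BOUND", rxn.lower_bound),
            ("UPPER_BOUND", rxn.upper_bound),
            ("OBJECTIVE_COEFFICIENT", 1.0 if rid == model.objective_id else 0.0),
            ("FLUX_VALUE", 0.0),
        ):
            par = law.createParameter()
            par.setId(pname)
            par.setValue(value)
            par.setUnits("mmol_per_gDW_per_hr")
        notes = {"KIND": rxn.kind, "SUBSYSTEM": rxn.subsystem}
        if rxn.gpr is not None:
            notes["GENE_ASSOCIATION"] = rxn.gpr.to_string()
        if rxn.likelihood is not None:
            notes["LIKELIHOOD"] = repr(rxn.likelihood)
        sr.setNotes(_notes(notes))

    if model.couplings:
        coup_lines = {
            f"COUPLING{i}": "{}|{}|{}|{}".format(
                c.name,
                ";".join(f"{k}:{v:g}" for k, v in sorted(c.abs_terms.items())),
                ";".join(f"{k}:{v:g}" for k, v in sorted(c.lin_terms.items())),
                c.ub,
            )
            for i, c in enumerate(model.couplings)
        }
        sbml_model.setNotes(_notes(coup_lines))

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"could not write SBML to {path}")


def read_sbml(path: str) -> MetabolicModel:
    doc = libsbml.readSBML(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ValueError(f"SBML parse error in {path}: {err.getMessage()}")
    if doc.getLevel() != 2:
        raise ValueError(f"only SBML level 2 is supported, got level {doc.getLevel()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ValueError(f"no model element in {path}")

    model = MetabolicModel(name=sbml_model.getId() or "sbml_model")
    species_ids = set()
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        species_ids.add(sp.getId())
        notes = _parse_notes(sp)
        comp = sp.getCompartment()
        if comp not in ("c0", "e0"):
            raise ValueError(f"unsupported compartment {comp!r} for species {sp.getId()}")
        model.add_metabolite(Metabolite(
            id=_from_sbml_id(sp.getId(), "M_"),
            name=sp.getName(),
            formula=notes.get("FORMULA", ""),
            charge=int(notes.get("CHARGE", "0")),
            compartment=comp,
            dgf_standard=float(notes["DGF"]) if "DGF" in notes else None,
            is_pseudo=notes.get("PSEUDO") == "1",
        ))

    objective = None
    for i in range(sbml_model.getNumReactions()):
        sr = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for ref, sign in [(sr.getReactant(j), -1.0) for j in range(sr.getNumReactants())] + \
                         [(sr.getProduct(j), 1.0) for j in range(sr.getNumProducts())]:
            if ref.getSpecies() not in species_ids:
                raise ValueError(
                    f"reaction {sr.getId()} references undefined species {ref.getSpecies()!r}"
                )
            mid = _from_sbml_id(ref.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) + sign * ref.getStoichiometry()
        if sr.getNumModifiers() > 0:
            raise ValueError(f"reaction {sr.getId()}: modifier species are not supported")
        lb, ub, obj = -1000.0, 1000.0, 0.0
        law = sr.getKineticLaw()
        if law is not None:
            for j in range(law.getNumParameters()):
                par = law.getParameter(j)
                if par.getId() == "LOWER_BOUND":
                    lb = par.getValue()
                elif par.getId() == "UPPER_BOUND":
                    ub = par.getValue()
                elif par.getId() == "OBJECTIVE_COEFFICIENT":
                    obj = par.getValue()
        elif not sr.getReversible():
            lb = 0.0
        notes = _parse_notes(sr)
        rid = _from_sbml_id(sr.getId(), "R_")
        gpr_text = notes.get("GENE_ASSOCIATION", "")
        model.add_reaction(Reaction(
            id=rid, name=sr.getName(), stoich=stoich,
            lower_bound=lb, upper_bound=ub,
            gpr=parse_gpr(gpr_text) if gpr_text.strip() else None,
            subsystem=notes.get("SUBSYSTEM", ""),
            kind=notes.get("KIND", "internal"),
            likelihood=float(notes["LIKELIHOOD"]) if "LIKELIHOOD" in notes else None,
        ))
        if obj:
            objective = rid
    model.objective_id = objective

    for key, value in sorted(_parse_notes(sbml_model).items()):
        if not key.startswith("COUPLING"):
            continue
        name, abs_t, lin_t, ub = value.split("|")
        def terms(cell):
            out = {}
            for item in cell.split(";"):
                if item:
                    k, v = item.rsplit(":", 1)
                    out[k] = float(v)
            return out
        model.couplings.append(Coupling(terms(abs_t), terms(lin_t), float(ub), name))
    model.validate()
    return model
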