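"""SBML Level 3 (FBC) import/export via COBRApy/libSBML.

Provenance (``gs_origin``) and the best supporting bitscore travel in
the reaction notes, so a round trip reproduces the model exactly.
"""

from __future__ import annotations

from .biochem import (
    BACKWARD,
    FORWARD,
    Metabolite,
    Reaction,
    REVERSIBLE,
    format_formula,
    parse_formula,
)
from .model import MetabolicModel


def to_cobra(model: MetabolicModel):
    import cobra

    if model.objective_id is None:
        raise ValueError("model has no objective reaction; cannot export")
    cm = cobra.Model(model.id)
    mets = {}
    for mid in sorted(model.metabolites):
        met = model.metabolites[mid]
        cmet = cobra.Metabolite(
            mid, name=met.name,
            formula=format_formula(met.formula) if met.formula else None,
            charge=met.charge, compartment=met.compartment)
        mets[mid] = cmet
    cm.add_metabolites(list(mets.values()))
    for rid in sorted(model.reactions):
        rxn = model.reactions[rid]
        crxn = cobra.Reaction(rid, name=rxn.name,
                              lower_bound=rxn.lb, upper_bound=rxn.ub)
        cm.add_reactions([crxn])
        crxn.add_metabolites({mets[m]: c for m, c in rxn.stoichiometry.items()})
        if rxn.gpr:
            crxn.gene_reaction_rule = rxn.gpr
        notes = {}
        if rxn.gs_origin is not None:
            notes["gs_origin"] = str(rxn.gs_origin)
        if rxn.evidence_bitscore is not None:
            notes["evidence_bitscore"] = repr(rxn.evidence_bitscore)
        if rxn.is_transport:
            notes["is_transport"] = "1"
        if rxn.is_spontaneous:
            notes["is_spontaneous"] = "1"
        if rxn.ec_numbers:
            notes["ec_numbers"] = ",".join(rxn.ec_numbers)
        crxn.notes = notes
        if rid == model.objective_id:
            crxn.objective_coefficient = 1.0
    return cm


def _reversibility(lb: float, ub: float) -> str:
    if lb < 0 and ub > 0:
        return REVERSIBLE
    if lb < 0:
        return BACKWARD
    return FORWARD


def from_cobra(cm) -> MetabolicModel:
    model = MetabolicModel(id=cm.id or "model")
    for cmet in sorted(cm.metabolites, key=lambda m: m.id):
        formula = parse_formula(cmet.formula) if cmet.formula else None
        model.metabolites[cmet.id] = Metabolite(
            id=cmet.id, name=cmet.name or "", formula=formula,
            charge=cmet.charge, compartment=cmet.compartment or "c0")
    objective_ids = [r.id for r in cm.reactions
                     if getattr(r, "objective_coefficient", 0)]
    for crxn in sorted(cm.reactions, key=lambda r: r.id):
        notes = crxn.notes or {}
        rxn = Reaction(
            id=crxn.id, name=crxn.name or "",
            stoichiometry={m.id: c for m, c in crxn.metabolites.items()},
            reversibility=_reversibility(crxn.lower_bound, crxn.upper_bound),
            lb=crxn.lower_bound, ub=crxn.upper_bound,
            ec_numbers=tuple(str(notes["ec_numbers"]).split(","))
            if notes.get("ec_numbers") else (),
            is_transport=str(notes.get("is_transport", "")) == "1",
            is_spontaneous=str(notes.get("is_spontaneous", "")) == "1",
            gpr=crxn.gene_reaction_rule or "",
            gs_origin=int(notes["gs_origin"]) if "gs_origin" in notes else None,
            evidence_bitscore=float(notes["evidence_bitscore"])
            if "evidence_bitscore" in notes else None,
        )
        model.reactions[rxn.id] = rxn
    model.objective_id = objective_ids[0] if objective_ids else None
    return model


def export_sbml(model: MetabolicModel, path) -> None:
    """Write SBML L3 with FBC bounds/objective; reaction notes carry
    provenance and evidence."""
    from cobra.io import write_sbml_model

    write_sbml_model(to_cobra(model), str(path))


def import_sbml(path) -> MetabolicModel:
    from cobra.io import read_sbml_model

    return from_cobra(read_sbml_model(str(path)))
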