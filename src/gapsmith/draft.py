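"""Draft model assembly from pathway, match, and transporter predictions.

Inclusion rules, each stamping a provenance code (``gs_origin``) on the
reaction; when several rules apply the lowest code wins:

* 0 — enzyme or transporter directly matched by homology
* 6 — biomass reaction
* 7 — exchange reaction
* 8 — diffusion of freely membrane-permeable compounds
* 9 — member of a predicted-present pathway without a direct match

Codes 1–4 are stamped later by the four gap-filling steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .biochem import (
    CYTOSOL,
    EXTRACELLULAR,
    GS_ORIGIN_BIOMASS,
    GS_ORIGIN_DIFFUSION,
    GS_ORIGIN_DIRECT,
    GS_ORIGIN_EXCHANGE,
    GS_ORIGIN_PATHWAY,
    IntegrityError,
    Reaction,
    ReactionDatabase,
    make_exchange,
)
from .complexes import ComplexCall, SubunitCatalog
from .evidence import EvidenceTable, HomologyHit, MatchThresholds, call_match
from .model import MetabolicModel
from .pathways import PathwayCall, SPONTANEOUS, VAGUE
from .transporters import DEFAULT_DIFFUSION_COMPOUNDS, diffusion_reactions

BIOMASS_ID = "bio1"
GRAM_VALUES = ("positive", "negative")


@dataclass
class BiomassTemplate:
    gram: str
    components: dict[str, float]      # metabolite id → mmol per gDW (consumed)
    energy_atp: float = 40.0          # ATP hydrolysis per gDW

    def __post_init__(self):
        if self.gram not in GRAM_VALUES:
            raise ValueError(f"gram must be one of {GRAM_VALUES}, got {self.gram!r}")
        if any(c <= 0 for c in self.components.values()):
            raise ValueError("biomass coefficients must be > 0")


def load_biomass_templates(path) -> dict[str, BiomassTemplate]:
    """TSV columns: gram, metabolite_id, coefficient. The pseudo-row
    metabolite_id=atp_energy gives the growth-associated ATP demand."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    by_gram: dict[str, dict] = {}
    for row in df.itertuples(index=False):
        d = by_gram.setdefault(row.gram, {"components": {}, "energy": 40.0})
        if row.metabolite_id == "atp_energy":
            d["energy"] = float(row.coefficient)
        else:
            d["components"][row.metabolite_id] = float(row.coefficient)
    return {g: BiomassTemplate(g, d["components"], d["energy"])
            for g, d in by_gram.items()}


def save_biomass_templates(templates: dict[str, BiomassTemplate], path) -> None:
    rows = []
    for gram in sorted(templates):
        t = templates[gram]
        rows.append({"gram": gram, "metabolite_id": "atp_energy",
                     "coefficient": t.energy_atp})
        for mid in sorted(t.components):
            rows.append({"gram": gram, "metabolite_id": mid,
                         "coefficient": t.components[mid]})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


_ENERGY = {"atp": -1.0, "h2o": -1.0, "adp": 1.0, "pi": 1.0, "h": 1.0}


def make_biomass_reaction(template: BiomassTemplate,
                          compartment: str = CYTOSOL) -> Reaction:
    stoich = {mid: -coef for mid, coef in template.components.items()}
    for base, sign in _ENERGY.items():
        mid = f"{base}_{compartment}"
        stoich[mid] = stoich.get(mid, 0.0) + sign * template.energy_atp
    return Reaction(
        id=BIOMASS_ID, name=f"Biomass (Gram-{template.gram})",
        stoichiometry=stoich, reversibility=">",
        gs_origin=GS_ORIGIN_BIOMASS)


def attach_biomass(model: MetabolicModel, gram: str,
                   template_db: dict[str, BiomassTemplate],
                   db: ReactionDatabase | None = None) -> MetabolicModel:
    """Add the Gram-appropriate biomass reaction and make it the objective.

    Component metabolites not yet in the model are pulled from *db* when
    given; otherwise they must already be present."""
    if gram not in template_db:
        raise ValueError(f"no biomass template for gram={gram!r}")
    out = model.copy()
    rxn = make_biomass_reaction(template_db[gram])
    known = set(out.metabolites) | (set(db.metabolites) if db else set())
    missing = sorted(m for m in rxn.stoichiometry if m not in known)
    if missing:
        raise IntegrityError(f"biomass components missing: {missing}")
    out.add_reaction(rxn, db)
    out.objective_id = BIOMASS_ID
    return out


def build_gprs(
    db: ReactionDatabase,
    hits: list[HomologyHit],
    thresholds: MatchThresholds | None = None,
    catalogs: dict[str, SubunitCatalog] | None = None,
) -> dict[str, str]:
    """Gene-protein-reaction strings from passing hits.

    One pseudo-gene per passing reference sequence. Isozymes (several
    passing sequences, or sequences in the same subunit pool) join with
    OR; recognised complex subunits join with AND across subunit labels.
    """
    t = thresholds or MatchThresholds()
    catalogs = catalogs or {}
    per_rxn: dict[str, dict[str | None, list[str]]] = {}
    for h in hits:
        for rid in h.reaction_ids:
            if rid not in db.reactions or not call_match(h, t, reaction_id=rid):
                continue
            label = h.subunit_label if rid in catalogs else None
            per_rxn.setdefault(rid, {}).setdefault(label, []).append(
                h.reference_seq_id)
    gprs: dict[str, str] = {}
    for rid, pools in per_rxn.items():
        catalog = catalogs.get(rid)
        if catalog is None or not catalog.counts:
            genes = sorted({g for pool in pools.values() for g in pool})
            gprs[rid] = " or ".join(genes)
        else:
            terms = []
            for label in sorted(catalog.counts):
                genes = sorted(set(pools.get(label, [])))
                if genes:
                    terms.append("(" + " or ".join(genes) + ")"
                                 if len(genes) > 1 else genes[0])
            gprs[rid] = " and ".join(terms)
    return gprs


def assemble_draft(
    pathway_calls: list[PathwayCall],
    evidence: EvidenceTable,
    transporter_selection: list[str],
    db: ReactionDatabase,
    gram: str,
    template_db: dict[str, BiomassTemplate],
    complex_calls: dict[str, ComplexCall] | None = None,
    gprs: dict[str, str] | None = None,
    diffusion_compounds=DEFAULT_DIFFUSION_COMPOUNDS,
    model_id: str = "draft",
) -> MetabolicModel:
    """Assemble the draft model; see the module docstring for the
    inclusion rules and provenance codes."""
    if gram not in GRAM_VALUES:
        raise ValueError(f"gram must be one of {GRAM_VALUES}, got {gram!r}")
    complex_calls = complex_calls or {}
    gprs = gprs or {}

    directly_matched: set[str] = set()
    for rid in sorted(db.reactions):
        if rid in complex_calls:
            if complex_calls[rid].present:
                directly_matched.add(rid)
        elif rid in evidence and evidence[rid].matched:
            directly_matched.add(rid)
    directly_matched.update(r for r in transporter_selection if r in db.reactions)

    spontaneous = {rid for rid, r in db.reactions.items() if r.is_spontaneous}

    pathway_members: set[str] = set()
    for call in pathway_calls:
        if call.present:
            pathway_members.update(
                r for r in call.statuses if r in db.reactions)

    origin: dict[str, int] = {}
    for rid in pathway_members:
        origin[rid] = GS_ORIGIN_PATHWAY
    for rid in directly_matched | spontaneous:
        origin[rid] = GS_ORIGIN_DIRECT

    model = MetabolicModel(id=model_id)
    for rid in sorted(origin):
        rxn = db.reactions[rid].copy()
        rxn.gs_origin = origin[rid]
        rec = evidence.get(rid)
        rxn.evidence_bitscore = rec.best_bitscore if rec else None
        if rid in gprs:
            rxn.gpr = gprs[rid]
        model.add_reaction(rxn, db)

    for rxn in diffusion_reactions(db, diffusion_compounds):
        if rxn.id not in model.reactions:
            model.add_reaction(rxn, db)

    for mid in sorted(model.metabolites):
        if model.metabolites[mid].compartment == EXTRACELLULAR:
            ex = make_exchange(mid)
            if ex.id not in model.reactions:
                model.add_reaction(ex)

    model = attach_biomass(model, gram, template_db, db)
    model.id = model_id
    return model
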