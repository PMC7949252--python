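"""Four-step gap-filling protocol on top of the evidence-weighted LP.

1. *Biomass*: make the model grow on the gap-filling medium, drawing on
   the full universal reaction set (provenance code 1).
2. *Biomass components*: on a minimal medium with one carbon source,
   ensure each biomass precursor is individually producible — run twice,
   with and without oxygen; only evidence-supported ("core") reactions
   may be added (code 2).
3. *Alternative energy sources*: per test substance, probe whether the
   substance can drive the recycling of reduced electron carriers
   (BIOLOG-style), again core-restricted (code 3).
4. *Metabolic products*: per test substance, probe whether the network
   can be completed to secrete it on the original medium (code 4).

Steps 2–4 deliberately reduce the dependence of the final network on the
particular gap-filling medium. Exchange reactions are medium-controlled
rather than evidence-gated, so they stay eligible in the core-restricted
steps (added exchanges are stamped with the exchange code 7).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .biochem import (
    GS_ORIGIN_EXCHANGE,
    Reaction,
    is_exchange,
)
from .draft import BIOMASS_ID
from .evidence import EvidenceTable
from .lp import FluxSolution, GapfillParams, fba, weighted_gapfill_lp
from .model import MetabolicModel, Medium
from .phenotype import add_esp_reactions
from .transporters import SubstanceMap

_ENERGY_BASES = {"atp", "h2o"}

DEFAULT_OXYGEN = "o2_e0"


def core_reactions(evidence: EvidenceTable,
                   params: GapfillParams | None = None) -> set[str]:
    """Reactions with genomic sequence evidence above the core threshold
    (strictly greater than the cutoff)."""
    p = params or GapfillParams()
    return {rid for rid, rec in evidence.items()
            if rec.best_bitscore > p.core_bitscore}


@dataclass
class StepRecord:
    step: int
    objective: str
    medium: str
    added: list[str] = field(default_factory=list)
    success: bool = True
    detail: dict = field(default_factory=dict)


@dataclass
class GapfillReport:
    steps: list[StepRecord] = field(default_factory=list)

    @property
    def all_added(self) -> list[str]:
        return [rid for s in self.steps for rid in s.added]


def extended_universal(universal: MetabolicModel,
                       model: MetabolicModel) -> MetabolicModel:
    """Universal model plus any model-only reactions (biomass, diffusion),
    objective taken from the model."""
    ext = universal.copy()
    for mid, met in model.metabolites.items():
        ext.metabolites.setdefault(mid, met)
    for rid, rxn in model.reactions.items():
        if rid not in ext.reactions:
            ext.add_reaction(rxn.copy())
    ext.objective_id = model.objective_id
    return ext


def _merge_additions(model: MetabolicModel, ext: MetabolicModel,
                     added: list[str], step: int,
                     bitscores: dict[str, float],
                     skip: set[str] = frozenset()) -> list[str]:
    """Copy added reactions into the model, stamping provenance. Added
    exchanges carry the exchange code, everything else the step number.
    Returns the merged ids."""
    merged = []
    for rid in added:
        if rid in skip or rid in model.reactions:
            continue
        rxn = ext.reactions[rid].copy()
        rxn.gs_origin = GS_ORIGIN_EXCHANGE if is_exchange(rxn) else step
        rxn.evidence_bitscore = bitscores.get(rid)
        for mid in rxn.stoichiometry:
            model.metabolites.setdefault(mid, ext.metabolites[mid])
        model.reactions[rxn.id] = rxn
        merged.append(rid)
    return merged


def _candidates_with_exchanges(ext: MetabolicModel, core: set[str],
                               extra: set[str] = frozenset()) -> set[str]:
    return core | extra | {r.id for r in ext.reactions.values() if is_exchange(r)}


def gapfill_step1_biomass(
    draft: MetabolicModel,
    universal: MetabolicModel,
    medium: Medium,
    evidence: EvidenceTable,
    params: GapfillParams | None = None,
    objective: str | None = None,
) -> tuple[MetabolicModel, StepRecord]:
    """Add every reaction essential for growth on the gap-filling medium,
    preferring high-evidence candidates (full universal reaction set)."""
    p = params or GapfillParams()
    objective = objective or draft.objective_id or BIOMASS_ID
    model = draft.copy()
    ext = extended_universal(universal, model)
    bitscores = evidence.bitscores()
    sol, added = weighted_gapfill_lp(
        ext, set(model.reactions), bitscores, objective, medium, p)
    merged = _merge_additions(model, ext, added, 1, bitscores)
    growth = fba(model, medium, objective)
    record = StepRecord(
        1, objective, medium.name, merged,
        success=growth.ok and growth.objective > p.flux_tolerance,
        detail={"growth": growth.objective if growth.ok else 0.0})
    if not record.success:
        raise RuntimeError(
            f"biomass unreachable after step 1 on medium {medium.name!r}; "
            "the universal model lacks a route (dead end upstream of biomass)")
    return model, record


def biomass_components(model: MetabolicModel,
                       objective: str | None = None) -> list[str]:
    """Biomass precursors = reactants of the biomass reaction, minus the
    energy couple (ATP + water)."""
    biomass = model.reactions[objective or model.objective_id]
    return sorted(m for m in biomass.reactants
                  if m.rsplit("_", 1)[0] not in _ENERGY_BASES)


def gapfill_step2_biomass_components(
    model: MetabolicModel,
    universal: MetabolicModel,
    core: set[str],
    minimal_medium: Medium,
    params: GapfillParams | None = None,
    carbon_source: str | None = "glc__D_e0",
    oxygen: str = DEFAULT_OXYGEN,
    bitscores: dict[str, float] | None = None,
) -> tuple[MetabolicModel, StepRecord]:
    """Ensure each biomass component is individually producible on a
    minimal medium, with and without oxygen; core reactions only."""
    p = params or GapfillParams()
    model = model.copy()
    base = minimal_medium
    if carbon_source and carbon_source in {
            next(iter(universal.reactions[rid].stoichiometry))
            for rid in universal.exchanges}:
        base = base.with_compound(carbon_source, 10.0)
    detail: dict[str, dict] = {}
    merged_all: list[str] = []
    for component in biomass_components(model):
        sink_id = f"SINK_{component}"
        comp_added: list[str] = []
        resolved = False
        for medium in (base, base.without_compound(oxygen)):
            ext = extended_universal(universal, model)
            ext.add_reaction(Reaction(
                id=sink_id, name=f"temporary sink for {component}",
                stoichiometry={component: -1.0}, reversibility=">"))
            candidates = _candidates_with_exchanges(ext, core, {sink_id})
            sol, added = weighted_gapfill_lp(
                ext, set(model.reactions), bitscores or {}, sink_id, medium,
                p, candidate_ids=candidates)
            if sol.fluxes.get(sink_id, 0.0) > p.flux_tolerance:
                resolved = True
                merged = _merge_additions(model, ext, added, 2,
                                          bitscores or {}, skip={sink_id})
                comp_added.extend(merged)
        merged_all.extend(comp_added)
        detail[component] = {"resolved": resolved, "added": comp_added}
    record = StepRecord(2, "biomass components", base.name, merged_all,
                        success=True, detail=detail)
    return model, record


def gapfill_step3_energy_sources(
    model: MetabolicModel,
    universal: MetabolicModel,
    core: set[str],
    substances: list[str],
    substance_map: SubstanceMap,
    minimal_medium: Medium,
    params: GapfillParams | None = None,
    bitscores: dict[str, float] | None = None,
) -> tuple[MetabolicModel, StepRecord]:
    """Per substance: can it drive recycling of reduced electron carriers
    on a minimal medium? Core-restricted; temporary recycling reactions
    are never kept."""
    p = params or GapfillParams()
    model = model.copy()
    detail: dict[str, dict] = {}
    merged_all: list[str] = []
    for name in substances:
        resolved = substance_map.resolve(name)
        if resolved is None:
            detail[name] = {"skipped": "unknown substance"}
            continue
        e_met = substance_map.compounds[resolved][1]
        ext = extended_universal(universal, model)
        if f"EX_{e_met}" not in ext.reactions:
            detail[name] = {"skipped": f"no exchange for {e_met}"}
            continue
        esp_ids = add_esp_reactions(ext)
        medium = minimal_medium.with_compound(e_met, 10.0)
        candidates = _candidates_with_exchanges(ext, core, set(esp_ids))
        sol, added = weighted_gapfill_lp(
            ext, set(model.reactions), bitscores or {}, esp_ids[-1], medium,
            p, candidate_ids=candidates)
        utilisable = sol.fluxes.get(esp_ids[-1], 0.0) > p.flux_tolerance
        merged = []
        if utilisable:
            merged = _merge_additions(model, ext, added, 3, bitscores or {},
                                      skip=set(esp_ids))
            merged_all.extend(merged)
        detail[name] = {"utilisable": utilisable, "added": merged}
    record = StepRecord(3, "electron-carrier recycling",
                        minimal_medium.name, merged_all, True, detail)
    return model, record


def gapfill_step4_products(
    model: MetabolicModel,
    universal: MetabolicModel,
    core: set[str],
    medium: Medium,
    substances: list[str],
    substance_map: SubstanceMap,
    params: GapfillParams | None = None,
    bitscores: dict[str, float] | None = None,
) -> tuple[MetabolicModel, StepRecord]:
    """Per substance: can the network be completed to secrete it on the
    original gap-filling medium? Core-restricted."""
    p = params or GapfillParams()
    model = model.copy()
    detail: dict[str, dict] = {}
    merged_all: list[str] = []
    for name in substances:
        resolved = substance_map.resolve(name)
        if resolved is None:
            detail[name] = {"skipped": "unknown substance"}
            continue
        e_met = substance_map.compounds[resolved][1]
        ex_id = f"EX_{e_met}"
        ext = extended_universal(universal, model)
        if ex_id not in ext.reactions:
            detail[name] = {"skipped": f"no exchange for {e_met}"}
            continue
        candidates = _candidates_with_exchanges(ext, core)
        sol, added = weighted_gapfill_lp(
            ext, set(model.reactions), bitscores or {}, ex_id, medium, p,
            candidate_ids=candidates)
        producible = sol.fluxes.get(ex_id, 0.0) > p.flux_tolerance
        merged = []
        if producible:
            merged = _merge_additions(model, ext, added, 4, bitscores or {})
            merged_all.extend(merged)
        detail[name] = {"producible": producible, "added": merged}
    record = StepRecord(4, "product formation", medium.name,
                        merged_all, True, detail)
    return model, record


def gapfill_protocol(
    draft: MetabolicModel,
    universal: MetabolicModel,
    medium: Medium,
    evidence: EvidenceTable,
    substances: list[str],
    substance_map: SubstanceMap,
    minimal_medium: Medium,
    params: GapfillParams | None = None,
    carbon_source: str | None = "glc__D_e0",
    oxygen: str = DEFAULT_OXYGEN,
    biomass_only: bool = False,
) -> tuple[MetabolicModel, GapfillReport]:
    """Run the full protocol (or step 1 only with ``biomass_only``)."""
    p = params or GapfillParams()
    report = GapfillReport()
    model, rec = gapfill_step1_biomass(draft, universal, medium, evidence, p)
    report.steps.append(rec)
    if biomass_only:
        return model, report
    core = core_reactions(evidence, p)
    bitscores = evidence.bitscores()
    model, rec = gapfill_step2_biomass_components(
        model, universal, core, minimal_medium, p, carbon_source, oxygen,
        bitscores=bitscores)
    report.steps.append(rec)
    model, rec = gapfill_step3_energy_sources(
        model, universal, core, substances, substance_map, minimal_medium, p,
        bitscores=bitscores)
    report.steps.append(rec)
    model, rec = gapfill_step4_products(
        model, universal, core, medium, substances, substance_map, p,
        bitscores=bitscores)
    report.steps.append(rec)
    return model, report
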