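"""End-to-end reconstruction driver: find → find-transport → draft → fill.

This is the library equivalent of the CLI's ``doall`` and the harness
the test fixtures run through.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .complexes import ComplexCall, SubunitCatalog, call_complex_from_hits
from .draft import BiomassTemplate, assemble_draft, build_gprs
from .evidence import (
    EvidenceTable,
    HomologyHit,
    MatchThresholds,
    build_evidence_table,
)
from .fixtures import ToyOrganism, ToyWorld
from .gapfill import GapfillReport, gapfill_protocol
from .lp import GapfillParams
from .model import MetabolicModel, Medium
from .pathways import PathwayCall, PathwayDef, PathwayParams, predict_pathways
from .transporters import (
    SubstanceMap,
    find_transporters,
    parse_transporter_hits,
)
from .universal import build_universal_model


@dataclass
class RunConfig:
    thresholds: MatchThresholds = field(default_factory=MatchThresholds)
    pathway_params: PathwayParams = field(default_factory=PathwayParams)
    gapfill_params: GapfillParams = field(default_factory=GapfillParams)
    gram: str = "negative"
    carbon_source: str = "glc__D_e0"
    oxygen: str = "o2_e0"
    biomass_only: bool = False  # step 1 only ("-q")


@dataclass
class FindResult:
    evidence: EvidenceTable
    complex_calls: dict[str, ComplexCall]
    pathway_calls: list[PathwayCall]


@dataclass
class PipelineResult:
    find: FindResult
    transporter_selection: list[str]
    draft: MetabolicModel
    filled: MetabolicModel
    report: GapfillReport


def run_find(hits: list[HomologyHit], pathway_defs: list[PathwayDef],
             catalogs: dict[str, SubunitCatalog] | None = None,
             thresholds: MatchThresholds | None = None,
             pathway_params: PathwayParams | None = None) -> FindResult:
    """Evidence reduction, complex calls, and pathway presence calls."""
    catalogs = catalogs or {}
    evidence = build_evidence_table(hits, thresholds)
    complex_calls = {}
    for rid, catalog in sorted(catalogs.items()):
        rxn_hits = [h for h in hits if rid in h.reaction_ids]
        if rxn_hits and catalog.counts:
            complex_calls[rid] = call_complex_from_hits(
                catalog, rxn_hits, thresholds)
    pathway_calls = predict_pathways(
        pathway_defs, evidence, complex_calls, pathway_params)
    return FindResult(evidence, complex_calls, pathway_calls)


def run_pipeline(
    db,
    pathway_defs: list[PathwayDef],
    substance_map: SubstanceMap,
    biomass_templates: dict[str, BiomassTemplate],
    hits: list[HomologyHit],
    transporter_hits: list[HomologyHit],
    medium: Medium,
    minimal_medium: Medium,
    substances: list[str],
    catalogs: dict[str, SubunitCatalog] | None = None,
    config: RunConfig | None = None,
    model_id: str = "model",
) -> PipelineResult:
    cfg = config or RunConfig()
    find = run_find(hits, pathway_defs, catalogs,
                    cfg.thresholds, cfg.pathway_params)
    t_hits = parse_transporter_hits(transporter_hits, substance_map)
    selection = find_transporters(t_hits, substance_map, db, cfg.thresholds)
    gprs = build_gprs(db, hits, cfg.thresholds, catalogs)
    draft = assemble_draft(
        find.pathway_calls, find.evidence, selection, db, cfg.gram,
        biomass_templates, find.complex_calls, gprs, model_id=model_id)
    universal = build_universal_model(db)
    filled, report = gapfill_protocol(
        draft, universal, medium, find.evidence, substances, substance_map,
        minimal_medium, cfg.gapfill_params, cfg.carbon_source, cfg.oxygen,
        biomass_only=cfg.biomass_only)
    filled.id = model_id
    return PipelineResult(find, selection, draft, filled, report)


def run_organism(world: ToyWorld, organism: ToyOrganism,
                 config: RunConfig | None = None) -> PipelineResult:
    """Convenience wrapper running the full pipeline on a toy organism."""
    cfg = config or RunConfig(gram=organism.gram)
    return run_pipeline(
        db=world.db,
        pathway_defs=world.pathway_defs,
        substance_map=world.substance_map,
        biomass_templates=world.biomass_templates,
        hits=organism.hits,
        transporter_hits=organism.transporter_hits,
        medium=world.media[organism.gapfill_medium],
        minimal_medium=world.media["m9_base"],
        substances=list(world.substances),
        catalogs=world.catalogs,
        config=cfg,
        model_id=organism.id,
    )
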