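"""Network-similarity score for models built from fragmented genomes.

Given a panel of reference models for the same species, the score is the
frequency-weighted recall of gene-associated reference reactions:

    T = Σ_i a_i · b_i / Σ_i b_i

over the union set of reactions with associated genes in the reference
panel, where b_i is the fraction of reference models containing reaction
i and a_i indicates whether the query model contains it. Biomass,
exchange, and diffusion pseudo-reactions never carry gene associations
and are excluded from the union set.
"""

from __future__ import annotations

from dataclasses import dataclass

from .biochem import (
    GS_ORIGIN_BIOMASS,
    GS_ORIGIN_DIFFUSION,
    GS_ORIGIN_EXCHANGE,
    is_exchange,
)
from .model import MetabolicModel

_EXCLUDED_ORIGINS = {GS_ORIGIN_BIOMASS, GS_ORIGIN_EXCHANGE, GS_ORIGIN_DIFFUSION}


@dataclass
class TsgbResult:
    score: float
    union_size: int
    frequencies: dict[str, float]     # b_i over the union set
    membership: dict[str, int]        # a_i ∈ {0, 1}


def _gene_associated_ids(model: MetabolicModel) -> set[str]:
    return {
        rid for rid, rxn in model.reactions.items()
        if rxn.gpr and not is_exchange(rxn)
        and rxn.gs_origin not in _EXCLUDED_ORIGINS
    }


def reference_reaction_frequencies(
        reference_models: list[MetabolicModel]) -> dict[str, float]:
    """b_i = fraction of reference models containing reaction i, over the
    union of gene-associated reactions."""
    if not reference_models:
        raise ValueError("empty reference panel")
    n = len(reference_models)
    sets = [_gene_associated_ids(m) for m in reference_models]
    union = sorted(set().union(*sets))
    return {rid: sum(rid in s for s in sets) / n for rid in union}


def tsgb_score(sgb_model: MetabolicModel,
               reference_models: list[MetabolicModel]) -> TsgbResult:
    frequencies = reference_reaction_frequencies(reference_models)
    denom = sum(frequencies.values())
    if denom == 0:
        raise ValueError("all reference frequencies are zero; score undefined")
    membership = {rid: int(rid in sgb_model.reactions) for rid in frequencies}
    score = sum(membership[r] * frequencies[r] for r in frequencies) / denom
    return TsgbResult(score, len(frequencies), frequencies, membership)
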