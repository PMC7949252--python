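"""Universal model assembly and curation checks (dead ends, energy cycles)."""

from __future__ import annotations

from dataclasses import dataclass

from .biochem import EXTRACELLULAR, ReactionDatabase, make_exchange
from .lp import FluxSolution, fba
from .model import MetabolicModel, Medium
from .transporters import DEFAULT_DIFFUSION_COMPOUNDS, diffusion_reactions


def build_universal_model(
        db: ReactionDatabase,
        diffusion_compounds=DEFAULT_DIFFUSION_COMPOUNDS) -> MetabolicModel:
    """One model holding every database reaction, an exchange for every
    extracellular metabolite, and diffusion carriers for freely
    membrane-permeable compounds.

    Dead ends are deliberately kept: the universal model is the reaction
    source for gap-filling, and pruning it would remove candidates.
    Reactions are inserted in lexicographic id order so repeated builds
    are identical.
    """
    db.validate()
    model = MetabolicModel(id="universal")
    for mid in sorted(db.metabolites):
        model.metabolites[mid] = db.metabolites[mid]
    for rid in sorted(db.reactions):
        model.add_reaction(db.reactions[rid].copy())
    for rxn in diffusion_reactions(db, diffusion_compounds):
        model.add_reaction(rxn)
    for mid in sorted(db.metabolites):
        if db.metabolites[mid].compartment == EXTRACELLULAR:
            model.add_reaction(make_exchange(mid))
    return model


def prune_dead_ends(model: MetabolicModel) -> MetabolicModel:
    """Remove dead-end metabolites and their reactions until fixed point.

    A metabolite is a dead end when, over the current reaction set and
    respecting flux bounds, it can only ever be produced or only ever be
    consumed (or touches no reaction at all). The input is not modified.
    """
    out = model.copy()
    changed = True
    while changed:
        changed = False
        producible: set[str] = set()
        consumable: set[str] = set()
        for rxn in out.reactions.values():
            fwd = rxn.ub > 0
            bwd = rxn.lb < 0
            for mid, coef in rxn.stoichiometry.items():
                if (coef > 0 and fwd) or (coef < 0 and bwd):
                    producible.add(mid)
                if (coef < 0 and fwd) or (coef > 0 and bwd):
                    consumable.add(mid)
        dead = {m for m in out.metabolites
                if not (m in producible and m in consumable)}
        if not dead:
            break
        for rid in [r.id for r in out.reactions.values()
                    if dead & set(r.stoichiometry)]:
            out.remove_reaction(rid)
            changed = True
        for mid in dead:
            del out.metabolites[mid]
            changed = True
    if out.objective_id not in out.reactions:
        out.objective_id = None
    return out


@dataclass
class CycleReport:
    objective: float
    flux_reactions: dict[str, float]

    @property
    def has_cycle(self) -> bool:
        return bool(self.flux_reactions)


def detect_energy_cycles(model: MetabolicModel,
                         energy_dissipation_reaction_id: str = "ATPM",
                         tolerance: float = 1e-9) -> CycleReport:
    """Maximize energy-dissipation flux with every uptake closed.

    A thermodynamically consistent network cannot dissipate energy
    without nutritional input, so the objective must be 0; anything
    larger exposes an energy-generating cycle, reported together with
    the reactions carrying flux.
    """
    if energy_dissipation_reaction_id not in model.reactions:
        raise ValueError(
            f"dissipation reaction absent: {energy_dissipation_reaction_id!r}")
    work = model.copy()
    for rid in work.exchanges:
        work.reactions[rid].lb = 0.0  # close uptake, keep secretion open
    sol: FluxSolution = fba(work, medium=None,
                            objective=energy_dissipation_reaction_id)
    if not sol.ok:
        raise RuntimeError(f"energy-cycle FBA {sol.status}")
    flux = {}
    if sol.objective > tolerance:
        flux = {rid: v for rid, v in sorted(sol.fluxes.items())
                if abs(v) > tolerance}
    return CycleReport(sol.objective, flux)
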