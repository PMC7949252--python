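"""In-memory genome-scale metabolic model and growth-medium containers."""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .biochem import (
    DEFAULT_BOUND,
    EXTRACELLULAR,
    Metabolite,
    Reaction,
    ReactionDatabase,
    IntegrityError,
    is_exchange,
)


@dataclass
class MetabolicModel:
    """Reactions + metabolites + objective.

    Reactions and metabolites are kept in insertion order; helpers that
    emit lists sort by id so that serialized output is deterministic.
    """

    id: str = "model"
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    objective_id: str | None = None

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=dict(self.metabolites),
            reactions={rid: r.copy() for rid, r in self.reactions.items()},
            objective_id=self.objective_id,
        )

    def add_reaction(self, rxn: Reaction, db: ReactionDatabase | None = None) -> None:
        """Add a reaction, pulling missing metabolites from *db* if given."""
        if rxn.id in self.reactions:
            raise IntegrityError(f"duplicate reaction id {rxn.id!r}")
        missing = [m for m in rxn.stoichiometry if m not in self.metabolites]
        for mid in missing:
            if db is None or mid not in db.metabolites:
                raise IntegrityError(
                    f"reaction {rxn.id} references unknown metabolite {mid!r}")
            self.metabolites[mid] = db.metabolites[mid]
        self.reactions[rxn.id] = rxn

    def remove_reaction(self, rxn_id: str) -> None:
        del self.reactions[rxn_id]

    @property
    def exchanges(self) -> list[str]:
        return sorted(r.id for r in self.reactions.values() if is_exchange(r))

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for r in self.reactions.values():
            if r.gpr:
                out |= set(re.findall(r"[\w.\-]+", r.gpr)) - {"and", "or"}
        return out

    def validate(self) -> None:
        if self.objective_id is not None and self.objective_id not in self.reactions:
            raise IntegrityError(f"objective {self.objective_id!r} not in model")
        for rxn in self.reactions.values():
            for mid in rxn.stoichiometry:
                if mid not in self.metabolites:
                    raise IntegrityError(
                        f"reaction {rxn.id} references unknown metabolite {mid!r}")


@dataclass
class Medium:
    """Maximum uptake rate per extracellular metabolite (mmol/gDW/h).

    ``default_rate`` is applied to every exchange when the medium is the
    complete medium (``"*"`` in the CSV dialect).
    """

    uptake: dict[str, float] = field(default_factory=dict)
    name: str = "medium"
    default_rate: float | None = None  # not None ⇒ complete medium

    def __post_init__(self):
        bad = {m: r for m, r in self.uptake.items() if r < 0}
        if bad:
            raise ValueError(f"negative uptake rates: {bad}")

    def rate_for(self, met_id: str) -> float:
        if met_id in self.uptake:
            return self.uptake[met_id]
        return self.default_rate if self.default_rate is not None else 0.0

    def with_compound(self, met_id: str, rate: float = 10.0) -> "Medium":
        up = dict(self.uptake)
        up[met_id] = rate
        return Medium(up, name=f"{self.name}+{met_id}", default_rate=self.default_rate)

    def without_compound(self, met_id: str) -> "Medium":
        up = {m: r for m, r in self.uptake.items() if m != met_id}
        return Medium(up, name=f"{self.name}-{met_id}", default_rate=self.default_rate)


def load_medium(path, name: str | None = None) -> Medium:
    """Read a medium CSV with columns compound_id, name, maxFlux.

    A row with compound_id ``"*"`` declares a complete medium: every
    exchange is opened at that row's rate unless listed explicitly.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = {"compound_id", "maxFlux"} - set(df.columns)
    if missing:
        raise ValueError(f"medium CSV: missing columns {sorted(missing)}")
    uptake: dict[str, float] = {}
    default = None
    for row in df.itertuples(index=False):
        rate = float(row.maxFlux)
        if row.compound_id == "*":
            default = rate
        else:
            uptake[row.compound_id] = rate
    return Medium(uptake, name=name or str(path), default_rate=default)


def save_medium(medium: Medium, path) -> None:
    rows = [{"compound_id": m, "name": m, "maxFlux": r}
            for m, r in sorted(medium.uptake.items())]
    if medium.default_rate is not None:
        rows.insert(0, {"compound_id": "*", "name": "complete",
                        "maxFlux": medium.default_rate})
    pd.DataFrame(rows, columns=["compound_id", "name", "maxFlux"]).to_csv(
        path, index=False)


def apply_medium(model: MetabolicModel, medium: Medium) -> list[str]:
    """Set exchange lower bounds from the medium (in place).

    Exchange lb = −uptake rate; secretion bounds are left open. Returns
    medium compounds without an exchange in the model (logged, not fatal).
    """
    missing = []
    for rid in model.exchanges:
        rxn = model.reactions[rid]
        met_id = next(iter(rxn.stoichiometry))
        rxn.lb = -medium.rate_for(met_id)
        rxn.ub = DEFAULT_BOUND
    model_mets = {next(iter(model.reactions[rid].stoichiometry))
                  for rid in model.exchanges}
    for met_id in medium.uptake:
        if met_id not in model_mets:
            missing.append(met_id)
    return missing
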