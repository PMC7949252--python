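"""Reaction/metabolite database: loading, validation, curation checks.

The database is the source of candidate reactions for draft assembly and
gap-filling. Reactions live in a two-compartment world (``c0`` cytosol,
``e0`` extracellular); transport reactions span both. Exchange reactions
are boundary pseudo-reactions with a single extracellular metabolite and
the convention *uptake = negative flux, secretion = positive flux*.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import pandas as pd

DEFAULT_COMPARTMENTS = frozenset({"c0", "e0"})
EXTRACELLULAR = "e0"
CYTOSOL = "c0"

#: flux bound magnitude for otherwise unbounded reactions (mmol/gDW/h)
DEFAULT_BOUND = 1000.0

#: provenance codes carried by model reactions (5 is reserved, 10 is
#: post-hoc manual curation and never produced here)
VALID_GS_ORIGINS = frozenset({0, 1, 2, 3, 4, 6, 7, 8, 9, 10})

GS_ORIGIN_DIRECT = 0
GS_ORIGIN_BIOMASS = 6
GS_ORIGIN_EXCHANGE = 7
GS_ORIGIN_DIFFUSION = 8
GS_ORIGIN_PATHWAY = 9

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormatError(ValueError):
    """A table does not conform to the documented dialect."""


class IntegrityError(ValueError):
    """Cross-references within a database are broken."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-notation formula string into an element→count map.

    Raises :class:`FormatError` on anything that is not a sequence of
    element symbols with optional counts.
    """
    formula = formula.strip()
    if not formula:
        raise FormatError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise FormatError(f"cannot parse formula {formula!r}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula):
        raise FormatError(f"cannot parse formula {formula!r}")
    return counts


def format_formula(counts: dict[str, int]) -> str:
    """Render an element map in Hill order (C, H, then alphabetical)."""
    def key(el: str):
        return {"C": (0, el), "H": (1, el)}.get(el, (2, el))
    return "".join(
        f"{el}{counts[el] if counts[el] != 1 else ''}"
        for el in sorted(counts, key=key)
        if counts[el]
    )


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    formula: dict[str, int] | None = None  # None = unknown composition
    charge: int | None = None
    compartment: str = CYTOSOL

    def __post_init__(self):
        if self.formula is not None and any(v < 0 for v in self.formula.values()):
            raise ValueError(f"negative element count in {self.id}")


FORWARD = ">"
BACKWARD = "<"
REVERSIBLE = "="


def _default_bounds(reversibility: str, bound: float = DEFAULT_BOUND):
    if reversibility == FORWARD:
        return 0.0, bound
    if reversibility == BACKWARD:
        return -bound, 0.0
    if reversibility == REVERSIBLE:
        return -bound, bound
    raise ValueError(f"unknown reversibility {reversibility!r}")


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]  # metabolite id → signed coefficient
    name: str = ""
    reversibility: str = REVERSIBLE
    lb: float | None = None
    ub: float | None = None
    ec_numbers: tuple[str, ...] = ()
    is_transport: bool = False
    is_spontaneous: bool = False
    gpr: str = ""
    gs_origin: int | None = None
    evidence_bitscore: float | None = None

    def __post_init__(self):
        if not self.stoichiometry:
            raise ValueError(f"reaction {self.id}: empty stoichiometry")
        lb, ub = _default_bounds(self.reversibility)
        if self.lb is None:
            self.lb = lb
        if self.ub is None:
            self.ub = ub
        if self.lb > self.ub:
            raise ValueError(f"reaction {self.id}: lb > ub")
        if self.gs_origin is not None and self.gs_origin not in VALID_GS_ORIGINS:
            raise ValueError(f"reaction {self.id}: invalid gs_origin {self.gs_origin}")

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))

    @property
    def reactants(self) -> dict[str, float]:
        return {m: -c for m, c in self.stoichiometry.items() if c < 0}

    @property
    def products(self) -> dict[str, float]:
        return {m: c for m, c in self.stoichiometry.items() if c > 0}


@dataclass
class ReactionDatabase:
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    compartments: frozenset[str] = DEFAULT_COMPARTMENTS

    def validate(self) -> None:
        """Check cross-references and compartment declarations."""
        for met in self.metabolites.values():
            if met.compartment not in self.compartments:
                raise IntegrityError(
                    f"metabolite {met.id}: undeclared compartment {met.compartment!r}"
                )
        for rxn in self.reactions.values():
            for mid in rxn.stoichiometry:
                if mid not in self.metabolites:
                    raise IntegrityError(
                        f"reaction {rxn.id} references unknown metabolite {mid!r}"
                    )

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise IntegrityError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise IntegrityError(f"duplicate reaction id {rxn.id!r}")
        self.reactions[rxn.id] = rxn


@dataclass(frozen=True)
class BalanceReport:
    reaction_id: str
    element_imbalance: dict[str, float]
    charge_imbalance: float | None
    status: str  # "balanced" | "unbalanced" | "unknown composition"

    @property
    def balanced(self) -> bool:
        return self.status == "balanced"


def _parse_stoichiometry(text: str) -> dict[str, float]:
    stoich: dict[str, float] = {}
    for part in str(text).split(";"):
        part = part.strip()
        if not part:
            continue
        met, _, coef = part.rpartition(":")
        if not met:
            raise FormatError(f"bad stoichiometry term {part!r}")
        stoich[met.strip()] = stoich.get(met.strip(), 0.0) + float(coef)
    return stoich


_REACTION_COLUMNS = ["id", "name", "stoichiometry", "reversibility",
                     "ec", "is_transport", "is_spontaneous"]
_METABOLITE_COLUMNS = ["id", "name", "formula", "charge", "compartment"]


def load_reaction_db(reactions_path, metabolites_path) -> ReactionDatabase:
    """Load a database from the two TSV tables and cross-validate it.

    Parse problems are reported with 1-based data row numbers.
    """
    db = ReactionDatabase()
    mets = pd.read_csv(metabolites_path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_METABOLITE_COLUMNS) - set(mets.columns)
    if missing:
        raise FormatError(f"metabolites table: missing columns {sorted(missing)}")
    for i, row in enumerate(mets.itertuples(index=False), start=1):
        try:
            formula = parse_formula(row.formula) if row.formula else None
            charge = int(row.charge) if row.charge != "" else None
            db.add_metabolite(Metabolite(
                id=row.id, name=row.name, formula=formula,
                charge=charge, compartment=row.compartment,
            ))
        except (ValueError, FormatError) as exc:
            raise FormatError(f"metabolites table row {i}: {exc}") from exc

    rxns = pd.read_csv(reactions_path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_REACTION_COLUMNS) - set(rxns.columns)
    if missing:
        raise FormatError(f"reactions table: missing columns {sorted(missing)}")
    for i, row in enumerate(rxns.itertuples(index=False), start=1):
        try:
            db.add_reaction(Reaction(
                id=row.id, name=row.name,
                stoichiometry=_parse_stoichiometry(row.stoichiometry),
                reversibility=row.reversibility,
                ec_numbers=tuple(e.strip() for e in row.ec.split(",") if e.strip()),
                is_transport=row.is_transport == "1",
                is_spontaneous=row.is_spontaneous == "1",
            ))
        except (ValueError, FormatError) as exc:
            raise FormatError(f"reactions table row {i}: {exc}") from exc
    db.validate()
    return db


def save_reaction_db(db: ReactionDatabase, reactions_path, metabolites_path) -> None:
    """Write the two TSV tables in the dialect `load_reaction_db` reads."""
    pd.DataFrame(
        [{
            "id": m.id, "name": m.name,
            "formula": format_formula(m.formula) if m.formula else "",
            "charge": "" if m.charge is None else m.charge,
            "compartment": m.compartment,
        } for m in sorted(db.metabolites.values(), key=lambda m: m.id)]
    ).to_csv(metabolites_path, sep="\t", index=False)
    pd.DataFrame(
        [{
            "id": r.id, "name": r.name,
            "stoichiometry": ";".join(
                f"{m}:{c:g}" for m, c in sorted(r.stoichiometry.items())),
            "reversibility": r.reversibility,
            "ec": ",".join(r.ec_numbers),
            "is_transport": int(r.is_transport),
            "is_spontaneous": int(r.is_spontaneous),
        } for r in sorted(db.reactions.values(), key=lambda r: r.id)]
    ).to_csv(reactions_path, sep="\t", index=False)


def is_exchange(rxn: Reaction) -> bool:
    return len(rxn.stoichiometry) == 1


def is_biomass(rxn: Reaction) -> bool:
    return rxn.gs_origin == GS_ORIGIN_BIOMASS or rxn.id.lower().startswith("biomass")


def check_mass_charge_balance(rxn: Reaction, db: ReactionDatabase) -> BalanceReport:
    """Sum elements and charge over a reaction's stoichiometry.

    Exchange and biomass reactions are rejected outright: they are
    boundary/lumped pseudo-reactions and are not balanceable. Metabolites
    of unknown composition yield status ``"unknown composition"`` rather
    than a pass or fail.
    """
    if is_exchange(rxn):
        raise ValueError(f"reaction {rxn.id}: exchange not balanceable")
    if is_biomass(rxn):
        raise ValueError(f"reaction {rxn.id}: biomass not balanceable")
    elements: dict[str, float] = {}
    charge: float | None = 0.0
    unknown = False
    for mid, coef in rxn.stoichiometry.items():
        met = db.metabolites[mid]
        if met.formula is None:
            unknown = True
            continue
        for el, n in met.formula.items():
            elements[el] = elements.get(el, 0.0) + coef * n
        if met.charge is None:
            charge = None
        elif charge is not None:
            charge += coef * met.charge
    elements = {el: v for el, v in elements.items() if abs(v) > 1e-9}
    if unknown:
        return BalanceReport(rxn.id, elements, charge, "unknown composition")
    balanced = not elements and charge is not None and abs(charge) < 1e-9
    return BalanceReport(rxn.id, elements, charge,
                         "balanced" if balanced else "unbalanced")


def exchange_id(met_id: str) -> str:
    return f"EX_{met_id}"


def make_exchange(met_id: str) -> Reaction:
    """Boundary reaction {met: −1}; uptake negative, secretion positive."""
    return Reaction(
        id=exchange_id(met_id),
        name=f"Exchange of {met_id}",
        stoichiometry={met_id: -1.0},
        reversibility=REVERSIBLE,
        gs_origin=GS_ORIGIN_EXCHANGE,
    )
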