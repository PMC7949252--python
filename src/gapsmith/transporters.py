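"""Transporter detection from TC-annotated homology hits and selection of
matching transport reactions.

Transporter classes follow the Transporter Classification system:
1 channels/pores, 2 electrochemical potential-driven carriers, 3 primary
active transporters, 4 group translocators. The class of an evidence hit
comes from the TC number in the reference FASTA header; the class of a
candidate transport reaction is inferred from name keywords or, failing
that, from its stoichiometry.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .biochem import CYTOSOL, EXTRACELLULAR, Reaction, ReactionDatabase
from .evidence import HomologyHit, MatchThresholds, call_match

SUPPORTED_CLASSES = (1, 2, 3, 4)

#: compounds assumed to cross membranes by diffusion; no transporter
#: evidence is required for them
DEFAULT_DIFFUSION_COMPOUNDS = ("h2", "o2", "co2", "h2o", "nh3")


def diffusion_reactions(db: ReactionDatabase,
                        compounds=DEFAULT_DIFFUSION_COMPOUNDS) -> list[Reaction]:
    """Reversible e0↔c0 carriers for freely diffusing compounds present
    in the database. Included in every draft and in the universal model
    (membrane crossing here needs no enzyme, so no evidence is asked)."""
    from .biochem import GS_ORIGIN_DIFFUSION
    out = []
    for base in sorted(compounds):
        e_id = f"{base}_{EXTRACELLULAR}"
        c_id = f"{base}_{CYTOSOL}"
        if e_id in db.metabolites and c_id in db.metabolites:
            out.append(Reaction(
                id=f"{base.upper()}tex", name=f"{base} diffusion",
                stoichiometry={e_id: -1.0, c_id: 1.0},
                reversibility="=", is_transport=True,
                gs_origin=GS_ORIGIN_DIFFUSION))
    return out

_TC_RE = re.compile(r"\b([1-9])\.([A-Z])\.(\d+)(?:\.(\d+))?(?:\.(\d+))?\b")

_KEYWORDS = [
    (1, ("channel", "pore")),
    (2, ("uniport", "symport", "antiport", "permease", "gradient")),
    (3, ("abc", "atpase", "atp")),
    (4, ("pts",)),
]


class TransporterParseError(ValueError):
    pass


@dataclass(frozen=True)
class TransporterHit:
    tc_number: str
    tc_class: int
    substance: str
    hit: HomologyHit


@dataclass(frozen=True)
class TransportReactionCandidate:
    reaction_id: str
    tc_class: int
    substance: str            # normalized lowercase substance name
    source: str               # keyword | stoichiometry | manual


@dataclass
class SubstanceMap:
    """Normalized substance name → metabolite ids, with synonyms."""

    #: name → (cytosolic met id, extracellular met id)
    compounds: dict[str, tuple[str, str]] = field(default_factory=dict)
    synonyms: dict[str, str] = field(default_factory=dict)

    def resolve(self, name: str) -> str | None:
        key = name.strip().lower()
        if key in self.compounds:
            return key
        return self.synonyms.get(key)

    def substance_of_metabolite(self, met_id: str) -> str | None:
        for name, (c_id, e_id) in self.compounds.items():
            if met_id in (c_id, e_id):
                return name
        return None


def load_substance_map(path) -> SubstanceMap:
    """TSV columns: name, synonyms (comma-separated), met_cytosol, met_extracellular."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    sm = SubstanceMap()
    for row in df.itertuples(index=False):
        name = row.name.strip().lower()
        sm.compounds[name] = (row.met_cytosol, row.met_extracellular)
        for syn in row.synonyms.split(","):
            if syn.strip():
                sm.synonyms[syn.strip().lower()] = name
    return sm


def save_substance_map(sm: SubstanceMap, path) -> None:
    rev: dict[str, list[str]] = {n: [] for n in sm.compounds}
    for syn, name in sm.synonyms.items():
        rev[name].append(syn)
    pd.DataFrame([{
        "name": n, "synonyms": ",".join(sorted(rev[n])),
        "met_cytosol": sm.compounds[n][0],
        "met_extracellular": sm.compounds[n][1],
    } for n in sorted(sm.compounds)]).to_csv(path, sep="\t", index=False)


def parse_tc_class(fasta_header: str,
                   substance_map: SubstanceMap | None = None) -> tuple[str, int, str | None]:
    """Extract (tc_number, tc_class, substance) from a reference header.

    The class is the leading integer of the TC number; the substance is
    the first substance-map name (or synonym) occurring in the header
    text, None when no map is given or nothing matches.
    """
    m = _TC_RE.search(fasta_header)
    if not m:
        raise TransporterParseError(f"no TC number in header {fasta_header!r}")
    tc_number = m.group(0)
    tc_class = int(m.group(1))
    if tc_class not in SUPPORTED_CLASSES:
        raise TransporterParseError(
            f"unsupported transporter class {tc_class} in {tc_number!r}")
    substance = None
    if substance_map is not None:
        text = fasta_header.lower()
        names = sorted(set(substance_map.compounds) | set(substance_map.synonyms),
                       key=len, reverse=True)
        for name in names:
            if re.search(rf"(?<![a-z0-9]){re.escape(name)}(?![a-z0-9])", text):
                substance = substance_map.resolve(name)
                break
    return tc_number, tc_class, substance


def _crossing_substance(rxn: Reaction, db: ReactionDatabase,
                        substance_map: SubstanceMap) -> str | None:
    """Substance whose metabolite occurs on both sides of the reaction in
    different compartments; for group translocators (chemically modified
    during transport) fall back to the extracellular substrate consumed."""
    for name, (c_id, e_id) in sorted(substance_map.compounds.items()):
        coefs = rxn.stoichiometry
        if c_id in coefs and e_id in coefs and coefs[c_id] * coefs[e_id] < 0:
            return name
    consumed_e = [m for m, c in rxn.stoichiometry.items()
                  if c < 0 and db.metabolites[m].compartment == EXTRACELLULAR]
    candidates = [substance_map.substance_of_metabolite(m) for m in sorted(consumed_e)]
    candidates = [s for s in candidates if s]
    return candidates[0] if candidates else None


def _stoich_class(rxn: Reaction, db: ReactionDatabase) -> int | None:
    names = set(rxn.stoichiometry)

    def has(prefix):  # metabolite base name irrespective of compartment
        return any(m.rsplit("_", 1)[0] == prefix for m in names)

    if has("atp") and has("adp"):
        return 3
    if has("pep") and has("pyr"):
        return 4
    both_h = sum(1 for m in names if m.rsplit("_", 1)[0] in ("h", "na1"))
    if both_h >= 2:
        return 2
    return None


def classify_transport_reaction(
    rxn: Reaction, db: ReactionDatabase, substance_map: SubstanceMap,
    manual_overrides: dict[str, tuple[int, str]] | None = None,
) -> TransportReactionCandidate:
    """Infer transporter class and transported substance for a transport
    reaction (name keywords first, stoichiometry as fallback, manual
    overrides last)."""
    if not rxn.is_transport:
        raise ValueError(f"reaction {rxn.id} is not flagged is_transport")
    if manual_overrides and rxn.id in manual_overrides:
        tc_class, substance = manual_overrides[rxn.id]
        return TransportReactionCandidate(rxn.id, tc_class, substance, "manual")
    text = rxn.name.lower()
    tc_class = None
    source = "keyword"
    for cls, words in _KEYWORDS:
        if any(re.search(rf"(?<![a-z]){w}(?![a-z])", text) for w in words):
            tc_class = cls
            break
    if tc_class is None:
        tc_class = _stoich_class(rxn, db)
        source = "stoichiometry"
    if tc_class is None:
        raise ValueError(f"reaction {rxn.id}: transporter class unclassifiable")
    substance = _crossing_substance(rxn, db, substance_map)
    if substance is None:
        raise ValueError(f"reaction {rxn.id}: no substance crossing compartments")
    return TransportReactionCandidate(rxn.id, tc_class, substance, source)


def transport_candidates(
    db: ReactionDatabase, substance_map: SubstanceMap,
    manual_overrides: dict[str, tuple[int, str]] | None = None,
) -> list[TransportReactionCandidate]:
    """Classify every is_transport reaction that can be classified."""
    out = []
    for rid in sorted(db.reactions):
        rxn = db.reactions[rid]
        if not rxn.is_transport:
            continue
        try:
            out.append(classify_transport_reaction(
                rxn, db, substance_map, manual_overrides))
        except ValueError:
            continue
    return out


def parse_transporter_hits(hits: list[HomologyHit],
                           substance_map: SubstanceMap) -> list[TransporterHit]:
    """Interpret hit reference ids as TCDB-style headers; hits without a
    parsable TC number or a known substance are dropped."""
    out = []
    for h in hits:
        try:
            tc_number, tc_class, substance = parse_tc_class(
                h.reference_seq_id, substance_map)
        except TransporterParseError:
            continue
        if substance is None:
            continue
        out.append(TransporterHit(tc_number, tc_class, substance, h))
    return out


def find_transporters(
    transporter_hits: list[TransporterHit],
    substance_map: SubstanceMap,
    db: ReactionDatabase,
    thresholds: MatchThresholds | None = None,
    manual_overrides: dict[str, tuple[int, str]] | None = None,
) -> list[str]:
    """Select transport reactions supported by passing transporter hits.

    For every (substance, class) with a passing hit, candidate reactions
    of that class transporting that substance are selected; when the
    detected class has no candidate, the other classes are tried in
    ascending class order. Output is deduplicated, lexicographic, and
    independent of hit order.
    """
    t = thresholds or MatchThresholds()
    candidates = transport_candidates(db, substance_map, manual_overrides)
    by_substance: dict[str, dict[int, list[str]]] = {}
    for c in candidates:
        by_substance.setdefault(c.substance, {}).setdefault(c.tc_class, []).append(
            c.reaction_id)
    wanted: set[tuple[str, int]] = set()
    for th in transporter_hits:
        if call_match(th.hit, t):
            wanted.add((th.substance, th.tc_class))
    selected: set[str] = set()
    for substance, tc_class in sorted(wanted):
        classes = by_substance.get(substance)
        if not classes:
            continue  # substance has no transport reaction in the database
        if tc_class in classes:
            selected.update(classes[tc_class])
        else:
            for cls in sorted(classes):
                selected.update(classes[cls])
                break
    return sorted(selected)


def load_manual_overrides(path) -> dict[str, tuple[int, str]]:
    """TSV columns: reaction_id, substance, type."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return {row.reaction_id: (int(row.type), row.substance.strip().lower())
            for row in df.itertuples(index=False)}
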