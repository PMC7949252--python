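"""Pathway/subsystem presence calls from per-reaction evidence.

A pathway is a small set of reactions, optionally with *key* reactions
(diagnostic steps) and *spontaneous* members (present without an
enzyme). Presence follows completeness rules: at least 80% of reactions
found, or — if the pathway has key reactions and all of them are found —
at least 2/3. Reactions without any reference sequence data are *vague*
and are excluded from the missing count as long as they stay below 1/3
of the pathway.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .complexes import ComplexCall
from .evidence import EvidenceTable

FOUND = "found"
VAGUE = "vague"
MISSING = "missing"
SPONTANEOUS = "spontaneous"


@dataclass(frozen=True)
class PathwayEntry:
    reaction_id: str
    ec: str = ""
    key: bool = False
    spontaneous: bool = False
    has_reference_sequences: bool = True


@dataclass
class PathwayDef:
    id: str
    name: str = ""
    entries: tuple[PathwayEntry, ...] = ()

    def __post_init__(self):
        if not self.entries:
            raise ValueError(f"pathway {self.id}: empty reaction list")

    @property
    def key_ids(self) -> set[str]:
        return {e.reaction_id for e in self.entries if e.key}


@dataclass
class PathwayParams:
    completeness_cutoff_no_hints: float = 0.80
    completeness_cutoff: float = 2.0 / 3.0   # applies when all keys found
    vague_cutoff: float = 1.0 / 3.0

    def __post_init__(self):
        for v in (self.completeness_cutoff_no_hints, self.completeness_cutoff,
                  self.vague_cutoff):
            if not 0 <= v <= 1:
                raise ValueError("pathway cutoffs must lie in [0, 1]")


@dataclass
class PathwayCall:
    pathway_id: str
    statuses: dict[str, str]
    completeness: float
    keys_all_found: bool
    present: bool

    @property
    def found_ids(self) -> set[str]:
        return {r for r, s in self.statuses.items() if s in (FOUND, SPONTANEOUS)}


def classify_reaction_status(entry: PathwayEntry, evidence: EvidenceTable,
                             complex_call: ComplexCall | None = None) -> str:
    """Status of one pathway member.

    Spontaneous members are present in any case; members without
    reference sequences are vague; otherwise found ⇔ matched (through
    the ordinary single-sequence call or, for complexes, the subunit
    vote)."""
    if entry.spontaneous:
        return SPONTANEOUS
    if not entry.has_reference_sequences:
        return VAGUE
    if complex_call is not None:
        return FOUND if complex_call.present else MISSING
    rec = evidence.get(entry.reaction_id)
    return FOUND if rec is not None and rec.matched else MISSING


def pathway_completeness(statuses: dict[str, str],
                         params: PathwayParams | None = None) -> float:
    """Fraction of the pathway found.

    Vague reactions are excluded from the denominator while they make up
    strictly less than the vague cutoff of the pathway; otherwise they
    count as missing."""
    p = params or PathwayParams()
    n = len(statuses)
    if n == 0:
        raise ValueError("empty status map")
    f = sum(1 for s in statuses.values() if s in (FOUND, SPONTANEOUS))
    v = sum(1 for s in statuses.values() if s == VAGUE)
    if v and v / n < p.vague_cutoff:
        return f / (n - v)
    return f / n


def call_pathway_presence(pwy: PathwayDef, statuses: dict[str, str],
                          params: PathwayParams | None = None) -> PathwayCall:
    p = params or PathwayParams()
    completeness = pathway_completeness(statuses, p)
    keys = pwy.key_ids
    keys_all_found = bool(keys) and all(statuses.get(k) == FOUND for k in keys)
    present = completeness >= p.completeness_cutoff_no_hints or (
        keys_all_found and completeness >= p.completeness_cutoff)
    return PathwayCall(pwy.id, statuses, completeness, keys_all_found, present)


def predict_pathways(
    pathway_db: list[PathwayDef],
    evidence: EvidenceTable,
    complex_calls: dict[str, ComplexCall] | None = None,
    params: PathwayParams | None = None,
) -> list[PathwayCall]:
    """One presence call per pathway, ordered by pathway id."""
    complex_calls = complex_calls or {}
    calls = []
    for pwy in sorted(pathway_db, key=lambda p: p.id):
        statuses = {
            e.reaction_id: classify_reaction_status(
                e, evidence, complex_calls.get(e.reaction_id))
            for e in pwy.entries
        }
        calls.append(call_pathway_presence(pwy, statuses, params))
    return calls


_PWY_COLUMNS = ["pathway_id", "name", "reaction_id", "ec", "key",
                "spontaneous", "has_seq"]


def load_pathway_db(path) -> list[PathwayDef]:
    """Read pathway definitions from the TSV dialect (one row per
    pathway member)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_PWY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pathway table: missing columns {sorted(missing)}")
    defs: dict[str, dict] = {}
    for row in df.itertuples(index=False):
        d = defs.setdefault(row.pathway_id, {"name": row.name, "entries": []})
        d["entries"].append(PathwayEntry(
            reaction_id=row.reaction_id, ec=row.ec,
            key=row.key == "1", spontaneous=row.spontaneous == "1",
            has_reference_sequences=row.has_seq != "0"))
    return [PathwayDef(pid, d["name"], tuple(d["entries"]))
            for pid, d in sorted(defs.items())]


def save_pathway_db(defs: list[PathwayDef], path) -> None:
    pd.DataFrame([{
        "pathway_id": p.id, "name": p.name, "reaction_id": e.reaction_id,
        "ec": e.ec, "key": int(e.key), "spontaneous": int(e.spontaneous),
        "has_seq": int(e.has_reference_sequences),
    } for p in defs for e in p.entries], columns=_PWY_COLUMNS).to_csv(
        path, sep="\t", index=False)


def save_pathway_calls(calls: list[PathwayCall], path) -> None:
    """Prediction output TSV: pathway, status, completeness, counts."""
    pd.DataFrame([{
        "pathway": c.pathway_id,
        "status": "present" if c.present else "absent",
        "completeness": round(c.completeness, 6),
        "found": len(c.found_ids),
        "total": len(c.statuses),
        "keys_found": int(c.keys_all_found),
    } for c in calls]).to_csv(path, sep="\t", index=False)
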