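"""Homology-search evidence: hit tables, match calls, per-reaction scores.

A *hit* is one alignment of a reference protein sequence against the
genome, carrying bitscore, reference coverage and identity. Hits reduce
to a per-reaction evidence table: the reaction's best bitscore b (used
by the gap-filling weights) and a binary *matched* call (bitscore and
coverage cutoffs, plus optional per-reaction exception criteria such as
a minimum identity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .biochem import FormatError


@dataclass(frozen=True)
class HomologyHit:
    reference_seq_id: str
    reaction_ids: tuple[str, ...]
    bitscore: float
    coverage: float   # percent of the reference sequence aligned
    identity: float = 100.0
    subunit_label: str | None = None  # canonical label, None = undefined

    def __post_init__(self):
        if self.bitscore < 0:
            raise ValueError(f"{self.reference_seq_id}: negative bitscore")
        if not 0 <= self.coverage <= 100:
            raise ValueError(f"{self.reference_seq_id}: coverage outside [0, 100]")
        if not 0 <= self.identity <= 100:
            raise ValueError(f"{self.reference_seq_id}: identity outside [0, 100]")


@dataclass
class MatchThresholds:
    min_bitscore: float = 200.0
    min_coverage_pct: float = 75.0
    #: reaction id → extra criteria, e.g. {"min_identity_pct": 75}
    exceptions: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.min_bitscore < 0 or self.min_coverage_pct < 0:
            raise ValueError("thresholds must be ≥ 0")


@dataclass
class EvidenceRecord:
    best_bitscore: float
    best_hit: HomologyHit
    matched: bool


class EvidenceTable(dict):
    """reaction id → :class:`EvidenceRecord`. Reactions without any hit
    are simply absent (downstream weighting treats them as no-evidence)."""

    def bitscores(self) -> dict[str, float]:
        return {rid: rec.best_bitscore for rid, rec in self.items()}

    def matched_ids(self) -> set[str]:
        return {rid for rid, rec in self.items() if rec.matched}


_HIT_COLUMNS = ["ref_seq_id", "reaction_ids", "bitscore",
                "coverage_pct", "identity_pct", "subunit_label"]


def parse_hit_table(path) -> list[HomologyHit]:
    """Read the tabular hit dialect (TSV, columns as in `_HIT_COLUMNS`).

    Malformed rows raise :class:`FormatError` carrying the 1-based data
    row number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_HIT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"hit table: missing columns {sorted(missing)}")
    hits = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            hits.append(HomologyHit(
                reference_seq_id=row.ref_seq_id,
                reaction_ids=tuple(
                    r.strip() for r in row.reaction_ids.split(",") if r.strip()),
                bitscore=float(row.bitscore),
                coverage=float(row.coverage_pct),
                identity=float(row.identity_pct) if row.identity_pct else 100.0,
                subunit_label=row.subunit_label or None,
            ))
        except ValueError as exc:
            raise FormatError(f"hit table row {i}: {exc}") from exc
    return hits


def save_hit_table(hits: list[HomologyHit], path) -> None:
    pd.DataFrame([{
        "ref_seq_id": h.reference_seq_id,
        "reaction_ids": ",".join(h.reaction_ids),
        "bitscore": h.bitscore,
        "coverage_pct": h.coverage,
        "identity_pct": h.identity,
        "subunit_label": h.subunit_label or "",
    } for h in hits], columns=_HIT_COLUMNS).to_csv(path, sep="\t", index=False)


def parse_blast_tabular(path, mapping_path, ref_lengths: dict[str, int]) -> list[HomologyHit]:
    """Read 12-column tabular alignment output plus a sidecar mapping
    (TSV: seq_id, reaction_ids) into hits; coverage = alignment length /
    reference length."""
    cols = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore"]
    df = pd.read_csv(path, sep="\t", names=cols, dtype=str)
    mapping = pd.read_csv(mapping_path, sep="\t", dtype=str)
    seq2rxn = {row.seq_id: tuple(r.strip() for r in row.reaction_ids.split(","))
               for row in mapping.itertuples(index=False)}
    hits = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.qseqid not in seq2rxn:
            continue
        if row.qseqid not in ref_lengths:
            raise FormatError(f"alignment row {i}: unknown reference length "
                              f"for {row.qseqid!r}")
        coverage = min(100.0, 100.0 * float(row.length) / ref_lengths[row.qseqid])
        hits.append(HomologyHit(
            reference_seq_id=row.qseqid,
            reaction_ids=seq2rxn[row.qseqid],
            bitscore=float(row.bitscore),
            coverage=coverage,
            identity=float(row.pident),
        ))
    return hits


def call_match(hit: HomologyHit, thresholds: MatchThresholds | None = None,
               reaction_id: str | None = None) -> bool:
    """Binary match call: bitscore and coverage cutoffs plus any
    per-reaction exception criteria."""
    t = thresholds or MatchThresholds()
    if hit.bitscore < t.min_bitscore or hit.coverage < t.min_coverage_pct:
        return False
    for rid in ([reaction_id] if reaction_id else hit.reaction_ids):
        extra = t.exceptions.get(rid, {})
        if "min_identity_pct" in extra and hit.identity < extra["min_identity_pct"]:
            return False
        if "min_bitscore" in extra and hit.bitscore < extra["min_bitscore"]:
            return False
        if "min_coverage_pct" in extra and hit.coverage < extra["min_coverage_pct"]:
            return False
    return True


def build_evidence_table(hits: list[HomologyHit],
                         thresholds: MatchThresholds | None = None) -> EvidenceTable:
    """Reduce hits to per-reaction best bitscore and match call.

    The best bitscore is the maximum over *all* hits mapping to the
    reaction, regardless of coverage — coverage gates only the binary
    match call. A reference sequence mapping to several reactions
    contributes its score to each of them.
    """
    t = thresholds or MatchThresholds()
    table = EvidenceTable()
    for hit in hits:
        for rid in hit.reaction_ids:
            rec = table.get(rid)
            if rec is None or hit.bitscore > rec.best_bitscore:
                matched = rec.matched if rec else False
                table[rid] = EvidenceRecord(hit.bitscore, hit, matched)
            if call_match(hit, t, reaction_id=rid):
                table[rid].matched = True
    return table
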