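"""Protein-complex subunit structure from FASTA headers, and presence calls.

Reference FASTA headers encode which subunit of a complex each sequence
belongs to ("... subunit beta", "... chain II"). Numbering systems are
homogenised to arabic numerals; a complex is considered present when
more than half of its recognised subunits have a passing hit, with hits
on unlabelled ("undefined subunit") entries tipping the balance at
exactly one half.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .evidence import HomologyHit, MatchThresholds, call_match

KEYWORDS = ("subunit", "chain", "polypeptide", "component")

_GREEK = ["alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta",
          "theta", "iota", "kappa", "lambda", "mu", "nu", "xi", "omicron",
          "pi", "rho", "sigma", "tau", "upsilon", "phi", "chi", "psi", "omega"]
_GREEK_NUM = {name: i + 1 for i, name in enumerate(_GREEK)}
_GREEK_NUM.update({chr(0x3B1 + i): i + 1 for i in range(25) if chr(0x3B1 + i) != "ς"})

_ROMAN = {"i": 1, "v": 5, "x": 10}


def _roman_to_int(text: str) -> int | None:
    if not text or not set(text) <= set("ivx"):
        return None
    total, prev = 0, 0
    for ch in reversed(text):
        val = _ROMAN[ch]
        total += val if val >= prev else -val
        prev = max(prev, val)
    return total if 1 <= total <= 20 else None


def homogenise_subunit_label(raw_fragment: str) -> str | None:
    """Map a numbering fragment to the canonical "subunit N" label.

    Roman numerals I–XX, greek letters (spelled out or unicode), arabic
    numerals, and letters A–H (→ 1–8) all map to the same canonical
    arabic form, case-insensitively. Returns None when the fragment
    carries no recognisable numbering (the caller records an undefined
    subunit).
    """
    token = raw_fragment.strip().split()[0].strip(".,;:()[]") if raw_fragment.strip() else ""
    token = token.lower()
    if not token:
        return None
    if token.isdigit():
        n = int(token)
        return f"subunit {n}" if n >= 1 else None
    roman = _roman_to_int(token)
    if roman is not None:
        return f"subunit {roman}"
    if token in _GREEK_NUM:
        return f"subunit {_GREEK_NUM[token]}"
    if len(token) == 1 and "a" <= token <= "h":
        return f"subunit {ord(token) - ord('a') + 1}"
    return None


_KEYWORD_RE = re.compile("|".join(KEYWORDS), re.IGNORECASE)


def label_from_header(header: str) -> str | None:
    """Canonical subunit label from a full FASTA header, or None."""
    m = _KEYWORD_RE.search(header)
    if not m:
        return None
    return homogenise_subunit_label(header[m.end():])


@dataclass
class SubunitCatalog:
    reaction_id: str
    counts: dict[str, int] = field(default_factory=dict)  # canonical label → entries
    undefined_count: int = 0

    @property
    def n_subunits(self) -> int:
        return len(self.counts)


@dataclass
class ComplexCall:
    reaction_id: str
    n_subunits_recognized: int
    n_subunits_found: int
    undefined_hit: bool
    present: bool


def parse_subunits(fasta_headers: list[str], reaction_id: str,
                   min_count: int = 5,
                   dominance_fraction: float = 0.66) -> SubunitCatalog:
    """Count subunit labels over a reaction's reference headers.

    Two noise filters apply, in this order: labels seen fewer than
    *min_count* times are demoted to undefined, then if a single label
    covers at least *dominance_fraction* of the remaining labelled
    entries, all other labels are demoted as well. Unlabelled entries
    never count towards the subunit total.
    """
    counts: dict[str, int] = {}
    undefined = 0
    for header in fasta_headers:
        label = label_from_header(header)
        if label is None:
            undefined += 1
        else:
            counts[label] = counts.get(label, 0) + 1
    for label in [l for l, n in counts.items() if n < min_count]:
        undefined += counts.pop(label)
    total = sum(counts.values())
    if total:
        top = max(sorted(counts), key=lambda l: counts[l])
        if counts[top] / total >= dominance_fraction and len(counts) > 1:
            for label in [l for l in counts if l != top]:
                undefined += counts.pop(label)
    return SubunitCatalog(reaction_id, counts, undefined)


def call_complex_presence(
    catalog: SubunitCatalog,
    subunit_best_hits: dict[str, HomologyHit],
    thresholds: MatchThresholds | None = None,
    undefined_hits: list[HomologyHit] | None = None,
) -> ComplexCall:
    """Decide complex presence from per-subunit best hits.

    A subunit counts as found when its best hit passes the ordinary
    match call. Present ⇔ found fraction > 1/2, or exactly 1/2 with a
    passing hit in the undefined pool. With no recognised subunits the
    caller should fall back to single-sequence matching; here that case
    reports absent with zero subunits.
    """
    t = thresholds or MatchThresholds()
    n = catalog.n_subunits
    found = sum(
        1 for label in catalog.counts
        if label in subunit_best_hits
        and call_match(subunit_best_hits[label], t, reaction_id=catalog.reaction_id)
    )
    undef_pass = any(
        call_match(h, t, reaction_id=catalog.reaction_id)
        for h in (undefined_hits or []))
    if n == 0:
        present = False
    else:
        frac = found / n
        present = frac > 0.5 or (frac == 0.5 and undef_pass)
    return ComplexCall(catalog.reaction_id, n, found, undef_pass, present)


def call_complex_from_hits(
    catalog: SubunitCatalog,
    hits: list[HomologyHit],
    thresholds: MatchThresholds | None = None,
) -> ComplexCall:
    """Group a reaction's hits by subunit label and call presence.

    Hits whose label is not in the catalog (or is None) go to the
    undefined pool.
    """
    best: dict[str, HomologyHit] = {}
    undefined: list[HomologyHit] = []
    for h in hits:
        label = h.subunit_label
        if label in catalog.counts:
            if label not in best or h.bitscore > best[label].bitscore:
                best[label] = h
        else:
            undefined.append(h)
    return call_complex_presence(catalog, best, thresholds, undefined)
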