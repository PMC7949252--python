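"""Pathway completeness rules and presence calls."""

import numpy as np
import pytest

from gapsmith.evidence import EvidenceRecord, EvidenceTable, HomologyHit
from gapsmith.pathways import (
    FOUND,
    MISSING,
    SPONTANEOUS,
    VAGUE,
    PathwayDef,
    PathwayEntry,
    PathwayParams,
    call_pathway_presence,
    classify_reaction_status,
    load_pathway_db,
    pathway_completeness,
    predict_pathways,
    save_pathway_db,
)


def _ev(rid, bitscore, matched):
    h = HomologyHit("s", (rid,), bitscore, 80.0, 90.0)
    table = EvidenceTable()
    table[rid] = EvidenceRecord(bitscore, h, matched)
    return table


def test_status_classification():
    spont = PathwayEntry("r1", spontaneous=True)
    assert classify_reaction_status(spont, EvidenceTable()) == SPONTANEOUS
    vague = PathwayEntry("r2", has_reference_sequences=False)
    assert classify_reaction_status(vague, EvidenceTable()) == VAGUE
    entry = PathwayEntry("r3")
    assert classify_reaction_status(entry, _ev("r3", 240, True)) == FOUND
    assert classify_reaction_status(entry, _ev("r3", 140, False)) == MISSING
    assert classify_reaction_status(entry, EvidenceTable()) == MISSING


def _statuses(found, vague, missing, spontaneous=0):
    out = {}
    for i in range(found):
        out[f"f{i}"] = FOUND
    for i in range(vague):
        out[f"v{i}"] = VAGUE
    for i in range(missing):
        out[f"m{i}"] = MISSING
    for i in range(spontaneous):
        out[f"s{i}"] = SPONTANEOUS
    return out


@pytest.mark.parametrize("found,vague,missing,expected", [
    (8, 0, 2, 0.8),          # plain fraction
    (5, 3, 2, 5 / 7),        # 3/10 vague < 1/3 → excluded from denominator
    (2, 3, 1, 2 / 6),        # 3/6 vague ≥ 1/3 → vague count as missing
    (4, 0, 0, 1.0),
])
def test_completeness_vague_rule(found, vague, missing, expected):
    c = pathway_completeness(_statuses(found, vague, missing))
    assert c == pytest.approx(expected)


def test_spontaneous_count_as_found():
    c = pathway_completeness(_statuses(3, 0, 1, spontaneous=1))
    assert c == pytest.approx(4 / 5)


def test_completeness_empty_errors():
    with pytest.raises(ValueError):
        pathway_completeness({})


def test_vague_cutoff_zero_disables_exclusion():
    params = PathwayParams(vague_cutoff=0.0)
    c = pathway_completeness(_statuses(5, 3, 2), params)
    assert c == pytest.approx(0.5)


def _pwy(n, keys=()):
    return PathwayDef("P", "p", tuple(
        PathwayEntry(f"f{i}" if i < n else f"m{i}", key=(f"f{i}" in keys or
                                                         f"m{i}" in keys))
        for i in range(n)))


def test_presence_eighty_percent_rule():
    pwy = PathwayDef("P", "p", tuple(PathwayEntry(f"r{i}") for i in range(10)))
    statuses = {f"r{i}": FOUND if i < 8 else MISSING for i in range(10)}
    assert call_pathway_presence(pwy, statuses).present
    statuses["r7"] = MISSING
    assert not call_pathway_presence(pwy, statuses).present


def test_presence_key_reaction_relaxation():
    entries = tuple(PathwayEntry(f"r{i}", key=i < 2) for i in range(9))
    pwy = PathwayDef("P", "p", entries)
    # 6/9 found incl. both keys → 2/3 rule fires
    statuses = {f"r{i}": FOUND if i < 6 else MISSING for i in range(9)}
    call = call_pathway_presence(pwy, statuses)
    assert call.keys_all_found and call.present
    # one key missing → back to the 80% rule → absent
    statuses["r0"] = MISSING
    statuses["r6"] = FOUND
    call = call_pathway_presence(pwy, statuses)
    assert not call.keys_all_found and not call.present


def test_vague_key_does_not_satisfy_key_rule():
    entries = (PathwayEntry("k", key=True, has_reference_sequences=False),
               PathwayEntry("a"), PathwayEntry("b"), PathwayEntry("c"))
    pwy = PathwayDef("P", "p", entries)
    statuses = {"k": VAGUE, "a": FOUND, "b": FOUND, "c": FOUND}
    call = call_pathway_presence(pwy, statuses)
    assert not call.keys_all_found  # vague is not "found", even for a key
    assert call.present  # the 80% rule still fires: 3/3 after the vague drop
    assert call.completeness == pytest.approx(1.0)


def test_fixture_pathway_truth_table(world, fermenter_org, fermenter_result):
    calls = {c.pathway_id: c for c in fermenter_result.find.pathway_calls}
    truth = fermenter_org.truth
    for pid in truth["present_pathways"]:
        assert calls[pid].present, pid
    for pid in truth["absent_pathways"]:
        assert not calls[pid].present, pid
    assert calls["PWY_ACETATE"].completeness == pytest.approx(2 / 3)
    assert calls["PWY_FERM_LAC"].completeness == pytest.approx(0.5)


def test_empty_evidence_only_spontaneous_pathways(world):
    calls = predict_pathways(world.pathway_defs, EvidenceTable())
    present = {c.pathway_id for c in calls if c.present}
    assert present == set()  # no all-spontaneous pathway in the fixture set
    anap = next(c for c in calls if c.pathway_id == "PWY_ANAPLEROSIS")
    assert anap.statuses["HCO3E"] == SPONTANEOUS


def test_presence_monotone_under_added_evidence(world, fermenter_org):
    """Randomly strengthening evidence never flips a pathway from
    present to absent (200 random perturbations)."""
    from gapsmith.evidence import build_evidence_table
    from gapsmith.pipeline import run_find

    rng = np.random.default_rng(7)
    base = run_find(fermenter_org.hits, world.pathway_defs, world.catalogs)
    base_present = {c.pathway_id for c in base.pathway_calls if c.present}
    all_rids = [e.reaction_id for p in world.pathway_defs for e in p.entries]
    for trial in range(200):
        extra = [HomologyHit(f"x{trial}_{i}", (rng.choice(all_rids),),
                             float(rng.uniform(200, 500)),
                             float(rng.uniform(75, 100)), 90.0)
                 for i in range(rng.integers(1, 4))]
        grown = run_find(fermenter_org.hits + extra, world.pathway_defs,
                         world.catalogs)
        grown_present = {c.pathway_id for c in grown.pathway_calls if c.present}
        assert base_present <= grown_present


def test_pathway_db_roundtrip(world, tmp_path):
    save_pathway_db(world.pathway_defs, tmp_path / "p.tsv")
    back = load_pathway_db(tmp_path / "p.tsv")
    assert [p.id for p in back] == sorted(p.id for p in world.pathway_defs)
    by_id = {p.id: p for p in world.pathway_defs}
    for p in back:
        assert p.entries == by_id[p.id].entries
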