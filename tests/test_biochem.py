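"""Database loading, stoichiometric validators, and curation checks."""

import pytest

from gapsmith.biochem import (
    FormatError,
    IntegrityError,
    Metabolite,
    Reaction,
    check_mass_charge_balance,
    format_formula,
    is_exchange,
    load_reaction_db,
    make_exchange,
    parse_formula,
    save_reaction_db,
)
from gapsmith.fixtures import make_corrupted_db, make_toy_world
from gapsmith.model import MetabolicModel
from gapsmith.universal import (
    build_universal_model,
    detect_energy_cycles,
    prune_dead_ends,
)


@pytest.mark.parametrize("text,expected", [
    ("C6H12O6", {"C": 6, "H": 12, "O": 6}),
    ("H", {"H": 1}),
    ("HO4P", {"H": 1, "O": 4, "P": 1}),
    ("C10H12N5O13P3", {"C": 10, "H": 12, "N": 5, "O": 13, "P": 3}),
])
def test_formula_roundtrip(text, expected):
    assert parse_formula(text) == expected
    assert parse_formula(format_formula(expected)) == expected


@pytest.mark.parametrize("bad", ["", "6CH", "C6H12O6!", "c6h12"])
def test_formula_rejects_garbage(bad):
    with pytest.raises(FormatError):
        parse_formula(bad)


def test_load_reaction_db_roundtrip(world, tmp_path):
    save_reaction_db(world.db, tmp_path / "r.tsv", tmp_path / "m.tsv")
    db = load_reaction_db(tmp_path / "r.tsv", tmp_path / "m.tsv")
    assert len(db.reactions) == len(world.db.reactions) == 49
    assert len(db.metabolites) == len(world.db.metabolites) == 64
    for rid, rxn in world.db.reactions.items():
        assert db.reactions[rid].stoichiometry == rxn.stoichiometry
        assert db.reactions[rid].reversibility == rxn.reversibility


def test_load_empty_reactions_table(tmp_path):
    (tmp_path / "r.tsv").write_text(
        "id\tname\tstoichiometry\treversibility\tec\tis_transport\tis_spontaneous\n")
    (tmp_path / "m.tsv").write_text("id\tname\tformula\tcharge\tcompartment\n")
    db = load_reaction_db(tmp_path / "r.tsv", tmp_path / "m.tsv")
    assert len(db.reactions) == 0


def test_dangling_metabolite_reference_is_named(tmp_path):
    (tmp_path / "m.tsv").write_text(
        "id\tname\tformula\tcharge\tcompartment\n"
        "a_c0\ta\tC\t0\tc0\n")
    (tmp_path / "r.tsv").write_text(
        "id\tname\tstoichiometry\treversibility\tec\tis_transport\tis_spontaneous\n"
        "R1\tr1\ta_c0:-1;cpdX:1\t=\t\t0\t0\n")
    with pytest.raises(IntegrityError, match="cpdX"):
        load_reaction_db(tmp_path / "r.tsv", tmp_path / "m.tsv")


def test_missing_column_is_format_error(tmp_path):
    (tmp_path / "m.tsv").write_text("id\tname\tformula\tcharge\tcompartment\n")
    (tmp_path / "r.tsv").write_text("id\tname\n")
    with pytest.raises(FormatError, match="missing columns"):
        load_reaction_db(tmp_path / "r.tsv", tmp_path / "m.tsv")


def test_whole_fixture_database_is_balanced(world):
    """Every non-exchange, non-biomass reaction passes the mass/charge
    validator — the curation invariant of the shipped database."""
    for rxn in world.db.reactions.values():
        report = check_mass_charge_balance(rxn, world.db)
        assert report.balanced, (rxn.id, report)


def test_missing_proton_shows_charge_imbalance(world):
    rxn = Reaction(id="PFK_nohplus", stoichiometry={
        "f6p_c0": -1, "atp_c0": -1, "fdp_c0": 1, "adp_c0": 1})
    report = check_mass_charge_balance(rxn, world.db)
    assert not report.balanced
    assert report.charge_imbalance == -1
    assert report.element_imbalance == {"H": -1}


def test_exchange_not_balanceable(world):
    with pytest.raises(ValueError, match="exchange"):
        check_mass_charge_balance(make_exchange("glc__D_e0"), world.db)


def test_unknown_formula_reported_as_unknown(world):
    db = make_corrupted_db(world)  # fresh copy we can extend
    db.add_metabolite(Metabolite(id="mystery_c0", formula=None, charge=None))
    rxn = Reaction(id="RX", stoichiometry={"mystery_c0": -1, "pyr_c0": 1})
    report = check_mass_charge_balance(rxn, db)
    assert report.status == "unknown composition"
    assert not report.balanced


def test_universal_model_composition(world, universal):
    n_extra = sum(1 for m in world.db.metabolites.values()
                  if m.compartment == "e0")
    n_diffusion = 5
    assert len(universal.reactions) == \
        len(world.db.reactions) + n_extra + n_diffusion
    assert all(is_exchange(universal.reactions[f"EX_{m.id}"])
               for m in world.db.metabolites.values() if m.compartment == "e0")


def test_universal_model_deterministic(world):
    a = build_universal_model(world.db)
    b = build_universal_model(world.db)
    assert list(a.reactions) == list(b.reactions)
    n_db = len(world.db.reactions)
    assert list(a.reactions)[:n_db] == sorted(world.db.reactions)
    assert all(a.reactions[r].stoichiometry == b.reactions[r].stoichiometry
               for r in a.reactions)


def test_prune_dead_end_chain():
    model = MetabolicModel()
    for mid in ("a_c0", "b_c0", "c_c0"):
        model.metabolites[mid] = Metabolite(id=mid)
    model.reactions["AB"] = Reaction(id="AB", stoichiometry={"a_c0": -1, "b_c0": 1},
                                     reversibility=">")
    model.reactions["BC"] = Reaction(id="BC", stoichiometry={"b_c0": -1, "c_c0": 1},
                                     reversibility=">")
    pruned = prune_dead_ends(model)
    assert not pruned.reactions and not pruned.metabolites
    assert len(model.reactions) == 2  # original untouched


def test_prune_idempotent_and_monotone(universal):
    once = prune_dead_ends(universal)
    twice = prune_dead_ends(once)
    assert len(once.reactions) <= len(universal.reactions)
    assert set(twice.reactions) == set(once.reactions)


def test_energy_cycle_clean_database(universal):
    report = detect_energy_cycles(universal, "ATPM")
    assert report.objective <= 1e-9
    assert not report.has_cycle


def test_energy_cycle_detected_in_corrupted_database(world):
    """A mis-annotated ATP synthase copy creates free ATP synthesis; the
    check must report positive dissipation and name the cycle."""
    uni = build_universal_model(make_corrupted_db(world))
    report = detect_energy_cycles(uni, "ATPM")
    assert report.objective > 1e-9
    assert "ATPS4r_misannotated" in report.flux_reactions
    assert "ATPM" in report.flux_reactions


def test_energy_cycle_requires_dissipation_reaction(universal):
    with pytest.raises(ValueError, match="dissipation reaction absent"):
        detect_energy_cycles(universal, "NOT_A_REACTION")
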