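"""Carbon sources, fermentation profiles, essentiality, and GPR logic."""

import itertools

import pytest

from gapsmith.phenotype import (
    GprParseError,
    contingency_metrics,
    evaluate_gpr,
    gpr_equivalence,
    gpr_genes,
    predict_fermentation_products,
    single_gene_deletions,
    test_carbon_source as carbon_source_assay,
)

TOL = 1e-6


def test_carbon_source_truth_table(world, fermenter_org, fermenter_model):
    minimal = world.media["m9_base"]
    for name in fermenter_org.truth["carbon_sources_positive"]:
        e_met = world.substance_map.compounds[name][1]
        ok, flux = carbon_source_assay(fermenter_model, minimal, e_met)
        assert ok and flux > TOL, name
    for name in fermenter_org.truth["carbon_sources_negative"]:
        e_met = world.substance_map.compounds[name][1]
        ok, flux = carbon_source_assay(fermenter_model, minimal, e_met)
        assert not ok, name


def test_carbon_source_assay_restores_model(world, fermenter_model):
    before = (len(fermenter_model.reactions), len(fermenter_model.metabolites))
    carbon_source_assay(fermenter_model, world.media["m9_base"], "glc__D_e0")
    after = (len(fermenter_model.reactions), len(fermenter_model.metabolites))
    assert before == after
    assert "ESP_DRAIN" not in fermenter_model.reactions


def test_carbon_source_without_exchange_errors(world, fermenter_model):
    with pytest.raises(ValueError, match="no exchange"):
        carbon_source_assay(fermenter_model, world.media["m9_base"],
                            "unobtainium_e0")


def test_fermentation_profile_anaerobic(world, fermenter_model):
    profile = predict_fermentation_products(
        fermenter_model, world.media["m9_glc_anaerobic"])
    assert profile.growth_rate > TOL
    organic = {m for m in profile.mtf_release
               if m.split("_")[0] in ("ac", "etoh", "lac__D", "for")}
    assert organic, "anaerobic growth must shed reduced by-products"
    for met, release in profile.mtf_release.items():
        assert release >= 0
        assert profile.fva_max_release[met] >= release - 1e-6
    # the gap-filled lactate branch is functional: lactate secretion is
    # reachable once a sliver of growth optimality is conceded
    from gapsmith.lp import fva
    ranges = fva(fermenter_model, world.media["m9_glc_anaerobic"],
                 optimum_fraction=0.99, reactions=["EX_lac__D_e0"])
    assert ranges["EX_lac__D_e0"][1] > TOL


def test_no_ethanol_under_aerobic_parsimony(world, fermenter_model):
    profile = predict_fermentation_products(fermenter_model,
                                            world.media["m9_glc"])
    assert "etoh_e0" not in profile.mtf_release
    assert profile.growth_rate > 2 * predict_fermentation_products(
        fermenter_model, world.media["m9_glc_anaerobic"]).growth_rate


def test_fermentation_without_growth_errors(world, fermenter_model):
    with pytest.raises(ValueError, match="no growth"):
        predict_fermentation_products(fermenter_model, world.media["m9_base"])


# --- GPR logic -------------------------------------------------------------

@pytest.mark.parametrize("gpr,deleted,expected", [
    ("g1 and g2", {"g1"}, False),
    ("g1 or g2", {"g1"}, True),
    ("(g1 and g2) or g3", {"g1", "g3"}, False),
    ("(g1 and g2) or g3", {"g2"}, True),
    ("g1", set(), True),
    ("", {"g1"}, True),  # no gene control
])
def test_evaluate_gpr(gpr, deleted, expected):
    assert evaluate_gpr(gpr, deleted) is expected


@pytest.mark.parametrize("bad", ["g1 and", "and g1", "(g1", "g1 g2", "()"])
def test_malformed_gpr_reports_position(bad):
    with pytest.raises(GprParseError, match="position"):
        evaluate_gpr(bad, set())


@pytest.mark.parametrize("a,b,expected", [
    ("(a and b) or (a and c)", "a and (b or c)", True),
    ("a and b", "a or b", False),
    ("a", "  a ", True),
    ("a or (b and c)", "(a or b) and (a or c)", True),
])
def test_gpr_equivalence(a, b, expected):
    assert gpr_equivalence(a, b) is expected


def test_gpr_equivalence_combinatorial_limit():
    genes = " or ".join(f"g{i}" for i in range(21))
    with pytest.raises(ValueError, match="limit"):
        gpr_equivalence(genes, "g0")


def test_gpr_truth_table_oracle_small_expressions():
    """Independent oracle: evaluate expressions of ≤ 4 genes through
    Python's own boolean semantics and compare every assignment."""
    genes = ["a", "b", "c", "d"]
    exprs = ["a", "a and b", "a or b", "(a and b) or c",
             "(a or b) and (c or d)", "a and b and c and d",
             "a or (b and (c or d))"]
    for expr in exprs:
        for values in itertools.product([False, True], repeat=4):
            env = dict(zip(genes, values))
            deleted = {g for g, v in env.items() if not v}
            assert evaluate_gpr(expr, deleted) is eval(expr, {}, env)


# --- essentiality ----------------------------------------------------------

@pytest.fixture(scope="module")
def deletions_m9(world, fermenter_model):
    return single_gene_deletions(fermenter_model, world.media["m9_glc"])


def test_essentiality_truth_table(fermenter_org, deletions_m9):
    for gene in fermenter_org.truth["essential_m9_glc"]:
        growth, essential = deletions_m9[gene]
        assert essential, gene
    for gene in fermenter_org.truth["nonessential_m9_glc"]:
        growth, essential = deletions_m9[gene]
        assert not essential, gene


def test_isozymes_and_complex_subunits(fermenter_org, deletions_m9):
    org = fermenter_org.id
    # OR-joined isozymes: each dispensable alone
    assert not deletions_m9[f"{org}_ACKr_iso1"][1]
    assert not deletions_m9[f"{org}_ACKr_iso2"][1]
    # AND-joined subunits of the sole glucose uptake system: each essential
    assert deletions_m9[f"{org}_ptsI"][1]
    assert deletions_m9[f"{org}_ptsH"][1]


def test_essentiality_threshold_robust(world, fermenter_model, deletions_m9):
    """The fixture's growth structure is binary, so the calls are stable
    across two orders of magnitude of the cutoff."""
    for threshold in (0.001, 0.05):
        redone = single_gene_deletions(fermenter_model, world.media["m9_glc"],
                                       growth_threshold=threshold)
        assert {g: v[1] for g, v in redone.items()} == \
            {g: v[1] for g, v in deletions_m9.items()}


def test_no_deletion_reproduces_wild_type(world, fermenter_model,
                                          deletions_m9):
    from gapsmith.lp import fba

    wild_type = fba(fermenter_model, world.media["m9_glc"]).objective
    best = max(v[0] for v in deletions_m9.values())
    assert best <= wild_type + 1e-6


def test_essential_on_rich_stays_essential_on_minimal(world, fermenter_model):
    """Fixture property: auxotrophy structure makes essentiality monotone
    under medium enrichment."""
    rich = single_gene_deletions(fermenter_model, world.media["complete"])
    minimal = single_gene_deletions(fermenter_model, world.media["m9_glc"])
    for gene, (_, essential) in rich.items():
        if essential:
            assert minimal[gene][1], gene


def test_contingency_metrics():
    predicted = {"a": True, "b": True, "c": False, "d": False}
    observed = {"a": True, "b": False, "c": False, "d": True}
    m = contingency_metrics(predicted, observed)
    assert (m["tp"], m["fp"], m["tn"], m["fn"]) == (1, 1, 1, 1)
    assert m["accuracy"] == pytest.approx(0.5)
    assert m["sensitivity"] == pytest.approx(0.5)
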