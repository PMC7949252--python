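"""FBA/MTF/FVA mechanics and the evidence-weighted gap-filling LP."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gapsmith.biochem import Metabolite, Reaction
from gapsmith.lp import (
    GapfillParams,
    evidence_weight,
    fba,
    fva,
    mtf,
    weighted_gapfill_lp,
)
from gapsmith.model import MetabolicModel, Medium

TOL = 1e-6


def _met(mid):
    return Metabolite(id=mid, compartment=mid.rsplit("_", 1)[1])


def _linear_model():
    """EX_s ⇄ s_e0 → s_c0 → p_c0 → sink (objective)."""
    m = MetabolicModel(id="tiny")
    for mid in ("s_e0", "s_c0", "p_c0"):
        m.metabolites[mid] = _met(mid)
    m.reactions["EX_s_e0"] = Reaction(id="EX_s_e0", stoichiometry={"s_e0": -1.0})
    m.reactions["T_s"] = Reaction(id="T_s", stoichiometry={"s_e0": -1, "s_c0": 1},
                                  reversibility=">")
    m.reactions["R_sp"] = Reaction(id="R_sp", stoichiometry={"s_c0": -1, "p_c0": 1},
                                   reversibility=">")
    m.reactions["SINK_p"] = Reaction(id="SINK_p", stoichiometry={"p_c0": -1},
                                     reversibility=">")
    m.objective_id = "SINK_p"
    return m


def test_fba_linear_chain_limited_by_uptake():
    m = _linear_model()
    sol = fba(m, Medium({"s_e0": 5.0}))
    assert sol.ok and sol.objective == pytest.approx(5.0)
    assert sol.fluxes["EX_s_e0"] == pytest.approx(-5.0)


def test_fba_closed_medium_no_flux():
    sol = fba(_linear_model(), Medium({}))
    assert sol.ok and sol.objective == pytest.approx(0.0)


def test_fba_missing_objective_errors():
    with pytest.raises(ValueError, match="objective"):
        fba(_linear_model(), Medium({}), objective="NOPE")


def test_fba_steady_state_and_bounds_hold(world, fermenter_model):
    from gapsmith.model import apply_medium

    sol = fba(fermenter_model, world.media["m9_glc"])
    assert sol.ok
    work = fermenter_model.copy()
    apply_medium(work, world.media["m9_glc"])
    balance = {mid: 0.0 for mid in work.metabolites}
    for rid, rxn in work.reactions.items():
        for mid, coef in rxn.stoichiometry.items():
            balance[mid] += coef * sol.fluxes[rid]
        assert rxn.lb - 1e-6 <= sol.fluxes[rid] <= rxn.ub + 1e-6
    assert max(abs(v) for v in balance.values()) < 1e-6


def test_fba_agrees_with_cobra_oracle(world, fermenter_model):
    """Independent cross-check: COBRApy/GLPK on the exported model must
    reproduce the HiGHS growth rate."""
    from gapsmith.model import apply_medium
    from gapsmith.sbml import to_cobra

    ours = fba(fermenter_model, world.media["m9_glc"]).objective
    work = fermenter_model.copy()
    apply_medium(work, world.media["m9_glc"])
    theirs = to_cobra(work).optimize().objective_value
    assert ours == pytest.approx(theirs, rel=1e-6)


def test_mtf_keeps_objective_and_reduces_total_flux(world, fermenter_model):
    medium = world.media["m9_glc_anaerobic"]
    plain = fba(fermenter_model, medium)
    parsimonious = mtf(fermenter_model, medium)
    assert parsimonious.objective == pytest.approx(plain.objective, rel=1e-6)
    assert (sum(abs(v) for v in parsimonious.fluxes.values())
            <= sum(abs(v) for v in plain.fluxes.values()) + 1e-6)


def test_mtf_silences_internal_loop():
    m = _linear_model()
    m.metabolites["q_c0"] = _met("q_c0")
    m.reactions["L1"] = Reaction(id="L1", stoichiometry={"s_c0": -1, "q_c0": 1})
    m.reactions["L2"] = Reaction(id="L2", stoichiometry={"q_c0": -1, "s_c0": 1})
    sol = mtf(m, Medium({"s_e0": 5.0}))
    assert sol.objective == pytest.approx(5.0)
    assert abs(sol.fluxes["L1"]) < TOL and abs(sol.fluxes["L2"]) < TOL


def test_fva_brackets_mtf_fluxes(world, fermenter_model):
    medium = world.media["m9_glc_anaerobic"]
    parsimonious = mtf(fermenter_model, medium)
    ranges = fva(fermenter_model, medium, reactions=fermenter_model.exchanges)
    for rid, (lo, hi) in ranges.items():
        assert lo - 1e-6 <= parsimonious.fluxes[rid] <= hi + 1e-6


def test_fva_blocked_reaction_is_zero():
    m = _linear_model()
    m.metabolites["z_c0"] = _met("z_c0")
    m.reactions["DEAD"] = Reaction(id="DEAD",
                                   stoichiometry={"p_c0": -1, "z_c0": 1},
                                   reversibility=">", lb=0, ub=0)
    ranges = fva(m, Medium({"s_e0": 5.0}), reactions=["DEAD"])
    assert ranges["DEAD"] == (pytest.approx(0.0), pytest.approx(0.0))


# --- evidence → weight mapping --------------------------------------------

def test_weight_endpoints_match_defaults():
    assert evidence_weight(30, in_draft=False) == 100.0
    assert evidence_weight(250, in_draft=False) == 0.005
    assert evidence_weight(125, in_draft=False) == pytest.approx(50.0025)


def test_weight_draft_membership_dominates():
    for b in (None, 0, 30, 125, 500):
        assert evidence_weight(b, in_draft=True) == 0.005


def test_weight_continuous_at_thresholds():
    p = GapfillParams()
    assert evidence_weight(p.l, False, p) == pytest.approx(p.w_max)
    assert evidence_weight(p.l - 1e-9, False, p) == pytest.approx(p.w_max)
    assert evidence_weight(p.u, False, p) == p.w_min
    assert evidence_weight(p.u - 1e-7, False, p) == pytest.approx(
        p.w_min, abs=1e-4)


def test_weight_no_evidence_is_maximal():
    assert evidence_weight(None, in_draft=False) == 100.0


@settings(derandomize=True, max_examples=200)
@given(st.floats(0, 400), st.floats(0, 400))
def test_weight_non_increasing(b1, b2):
    lo, hi = sorted((b1, b2))
    assert evidence_weight(lo, False) >= evidence_weight(hi, False)


# --- gap-filling LP --------------------------------------------------------

def _gap_universe():
    """Two parallel 2-step routes (planted bitscores 150 vs 20) plus a
    1-step no-evidence route from substrate to product."""
    uni = MetabolicModel(id="uni")
    for mid in ("s_e0", "s_c0", "m_c0", "n_c0", "p_c0"):
        uni.metabolites[mid] = _met(mid)
    def rxn(rid, stoich):
        uni.reactions[rid] = Reaction(id=rid, stoichiometry=stoich,
                                      reversibility=">")
    uni.reactions["EX_s_e0"] = Reaction(id="EX_s_e0",
                                        stoichiometry={"s_e0": -1.0})
    rxn("T_s", {"s_e0": -1, "s_c0": 1})
    rxn("RA1", {"s_c0": -1, "m_c0": 1})
    rxn("RA2", {"m_c0": -1, "p_c0": 1})
    rxn("RB1", {"s_c0": -1, "n_c0": 1})
    rxn("RB2", {"n_c0": -1, "p_c0": 1})
    rxn("RD", {"s_c0": -1, "p_c0": 1})
    rxn("SINK_p", {"p_c0": -1})
    uni.objective_id = "SINK_p"
    bitscores = {"RA1": 150.0, "RA2": 150.0, "RB1": 20.0, "RB2": 20.0}
    draft = {"EX_s_e0", "T_s", "SINK_p"}
    return uni, draft, bitscores


def _grows(uni, subset, draft):
    trial = MetabolicModel(id="t", metabolites=dict(uni.metabolites))
    for rid in draft | set(subset):
        trial.reactions[rid] = uni.reactions[rid].copy()
    trial.objective_id = "SINK_p"
    sol = fba(trial, Medium({"s_e0": 10.0}))
    return sol.ok and sol.objective > TOL


def test_gapfill_prefers_high_evidence_route():
    uni, draft, bitscores = _gap_universe()
    sol, added = weighted_gapfill_lp(uni, draft, bitscores, "SINK_p",
                                     Medium({"s_e0": 10.0}))
    assert added == ["RA1", "RA2"]
    assert sol.fluxes["SINK_p"] > TOL


def test_gapfill_single_gap_recovers_exactly_the_missing_reaction():
    uni, draft, bitscores = _gap_universe()
    # draft holds all of route A except RA2; no other route has evidence
    draft = draft | {"RA1"}
    del uni.reactions["RD"], uni.reactions["RB1"], uni.reactions["RB2"]
    sol, added = weighted_gapfill_lp(uni, draft, bitscores, "SINK_p",
                                     Medium({"s_e0": 10.0}))
    assert added == ["RA2"]


def test_gapfill_growing_draft_adds_no_penalised_reactions():
    uni, draft, _ = _gap_universe()
    draft = draft | {"RA1", "RA2"}  # already grows; everything else w_max
    sol, added = weighted_gapfill_lp(uni, draft, {}, "SINK_p",
                                     Medium({"s_e0": 10.0}))
    assert added == []
    assert sol.fluxes["SINK_p"] > TOL


def test_gapfill_added_set_is_weight_optimal_by_enumeration():
    """Brute force over all candidate subsets: no growing subset has a
    strictly smaller total weight than the LP's added set."""
    uni, draft, bitscores = _gap_universe()
    params = GapfillParams()
    _, added = weighted_gapfill_lp(uni, draft, bitscores, "SINK_p",
                                   Medium({"s_e0": 10.0}), params)
    candidates = sorted(set(uni.reactions) - draft)
    assert len(candidates) <= 12

    def weight_of(subset):
        return sum(evidence_weight(bitscores.get(r), False, params)
                   for r in subset)

    growing = [set(sub)
               for k in range(len(candidates) + 1)
               for sub in itertools.combinations(candidates, k)
               if _grows(uni, sub, draft)]
    best = min(map(weight_of, growing))
    assert _grows(uni, added, draft)
    assert weight_of(added) == pytest.approx(best)


def test_gapfill_infeasible_problem_raises():
    """A forced internal flux with no possible substrate supply makes the
    LP infeasible; the solver error must carry a diagnostic."""
    uni, draft, bitscores = _gap_universe()
    uni.reactions["FORCED"] = Reaction(
        id="FORCED", stoichiometry={"s_c0": -1, "p_c0": 1},
        reversibility=">", lb=1.0, ub=10.0)
    with pytest.raises(Exception, match="unreachable|infeasible"):
        # closed medium: no substrate can ever enter
        weighted_gapfill_lp(uni, draft | {"FORCED"}, bitscores, "SINK_p",
                            Medium({}))


def test_gapfill_result_restores_growth(single_gap_result, world):
    org, res = single_gap_result
    sol = fba(res.filled, world.media[org.gapfill_medium])
    assert sol.objective > TOL
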