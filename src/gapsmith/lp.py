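"""Constraint-based analysis: FBA, minimal total flux, FVA, and the
evidence-weighted gap-filling LP.

All solves go through a minimal linear-program contract
(:class:`LinearProgram`) so the simplex/IPM backend is swappable; the
shipped backend is HiGHS via :func:`scipy.optimize.milp` with every
variable continuous, which is deterministic for a fixed variable order.

The gap-filling objective is

    max  v_obj − c · Σ_i w_i |v_i|

over all reactions of the universal model, subject to S·v = 0 and the
flux bounds, with |v_i| linearized through nonnegative split variables.
The weight w_i falls from w_max to w_min linearly in the reaction's best
supporting bitscore b_i between the thresholds l and u; reactions already
in the draft always get w_min, reactions with no evidence get w_max.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .biochem import DEFAULT_BOUND, Reaction
from .model import MetabolicModel, Medium, apply_medium

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"


class SolverError(RuntimeError):
    pass


@dataclass
class GapfillParams:
    """Tunables of the evidence-weighted gap-filling LP (defaults as
    documented in the weight mapping above)."""

    c: float = 0.001            # weight of the Σ w|v| term in the objective
    w_min: float = 0.005
    w_max: float = 100.0
    l: float = 50.0             # bitscore below which weight is w_max
    u: float = 200.0            # bitscore above which weight is w_min
    core_bitscore: float = 50.0  # strict lower bound for core reactions
    flux_tolerance: float = 1e-6
    exempt_exchanges: bool = False  # drop exchanges from the weighted sum

    def __post_init__(self):
        if not (0 < self.w_min < self.w_max):
            raise ValueError("need 0 < w_min < w_max")
        if not self.l < self.u:
            raise ValueError("need l < u")
        if self.c <= 0:
            raise ValueError("need c > 0")


@dataclass
class FluxSolution:
    status: str
    objective: float | None = None
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == OPTIMAL


class LinearProgram:
    """Minimal LP contract: variables with bounds, constraint rows with
    row bounds, a linear objective, one solve. HiGHS-backed."""

    def __init__(self):
        self._lb: list[float] = []
        self._ub: list[float] = []
        self._names: list[str] = []
        self._rows: list[dict[int, float]] = []
        self._row_lb: list[float] = []
        self._row_ub: list[float] = []
        self._obj: dict[int, float] = {}
        self._sense = 1.0  # minimize

    def add_variable(self, name: str, lb: float, ub: float) -> int:
        self._names.append(name)
        self._lb.append(lb)
        self._ub.append(ub)
        return len(self._names) - 1

    def add_constraint(self, coeffs: dict[int, float],
                       lb: float = 0.0, ub: float = 0.0) -> None:
        self._rows.append(coeffs)
        self._row_lb.append(lb)
        self._row_ub.append(ub)

    def set_objective(self, coeffs: dict[int, float], sense: str = "max") -> None:
        self._obj = dict(coeffs)
        self._sense = -1.0 if sense == "max" else 1.0

    def solve(self) -> tuple[str, float | None, np.ndarray | None]:
        n = len(self._names)
        c = np.zeros(n)
        for j, v in self._obj.items():
            c[j] = self._sense * v
        if self._rows:
            data, ri, ci = [], [], []
            for i, row in enumerate(self._rows):
                for j, v in row.items():
                    ri.append(i)
                    ci.append(j)
                    data.append(v)
            a = sparse.csr_matrix((data, (ri, ci)), shape=(len(self._rows), n))
            constraints = LinearConstraint(a, self._row_lb, self._row_ub)
        else:
            constraints = ()
        res = milp(c, constraints=constraints,
                   bounds=Bounds(self._lb, self._ub),
                   integrality=np.zeros(n))
        if res.status == 0:
            return OPTIMAL, self._sense * res.fun, res.x
        if res.status == 2:
            return INFEASIBLE, None, None
        if res.status == 3:
            return UNBOUNDED, None, None
        raise SolverError(f"solver failed: {res.message}")


def _sorted_ids(model: MetabolicModel) -> tuple[list[str], list[str]]:
    return sorted(model.reactions), sorted(model.metabolites)


def _build_stoich_rows(lp: LinearProgram, model: MetabolicModel,
                       var_of: dict[str, dict[str, int]]) -> None:
    """One steady-state row per metabolite; v_i = plus − minus when a
    reaction has split variables."""
    rows: dict[str, dict[int, float]] = {m: {} for m in model.metabolites}
    for rid in sorted(model.reactions):
        rxn = model.reactions[rid]
        for mid, coef in rxn.stoichiometry.items():
            for var, sign in var_of[rid].items():
                rows[mid][var] = rows[mid].get(var, 0.0) + sign * coef
    for mid in sorted(rows):
        lp.add_constraint(rows[mid], 0.0, 0.0)


def _make_flux_vars(lp: LinearProgram, model: MetabolicModel,
                    split: bool) -> dict[str, dict[str, int]]:
    """Add flux variables; split reactions into v⁺, v⁻ ≥ 0 when asked.

    Returns per reaction a map variable-index → sign (+1 for forward
    part, −1 for backward part).
    """
    var_of: dict[str, dict[int, float]] = {}
    for rid in sorted(model.reactions):
        rxn = model.reactions[rid]
        if not split:
            j = lp.add_variable(rid, rxn.lb, rxn.ub)
            var_of[rid] = {j: 1.0}
        else:
            # bounds chosen so v⁺−v⁻ still honours lb > 0 or ub < 0
            jp = lp.add_variable(f"{rid}+", max(rxn.lb, 0.0), max(rxn.ub, 0.0))
            jn = lp.add_variable(f"{rid}-", max(-rxn.ub, 0.0), max(-rxn.lb, 0.0))
            var_of[rid] = {jp: 1.0, jn: -1.0}
    return var_of


def _extract_fluxes(model: MetabolicModel, var_of, x) -> dict[str, float]:
    return {rid: sum(sign * x[j] for j, sign in var_of[rid].items())
            for rid in model.reactions}


def fba(model: MetabolicModel, medium: Medium | None,
        objective: str | None = None) -> FluxSolution:
    """Maximize the objective flux subject to S·v = 0 and bounds."""
    objective = objective or model.objective_id
    if objective not in model.reactions:
        raise ValueError(f"objective reaction {objective!r} not in model")
    work = model.copy()
    if medium is not None:
        apply_medium(work, medium)
    lp = LinearProgram()
    var_of = _make_flux_vars(lp, work, split=False)
    _build_stoich_rows(lp, work, var_of)
    (j_obj,) = var_of[objective]
    lp.set_objective({j_obj: 1.0}, sense="max")
    status, obj, x = lp.solve()
    if status != OPTIMAL:
        return FluxSolution(status)
    return FluxSolution(OPTIMAL, obj, _extract_fluxes(work, var_of, x))


def mtf(model: MetabolicModel, medium: Medium | None,
        objective: str | None = None,
        optimum_fraction: float = 1.0) -> FluxSolution:
    """Minimize Σ|v| with the objective pinned at its FBA optimum.

    The pin allows a 1e−9 relative slack so the secondary LP is not
    infeasible from round-off. The reported objective value is the
    objective *flux*, not Σ|v|.
    """
    objective = objective or model.objective_id
    first = fba(model, medium, objective)
    if not first.ok:
        return first
    target = optimum_fraction * first.objective
    work = model.copy()
    if medium is not None:
        apply_medium(work, medium)
    lp = LinearProgram()
    var_of = _make_flux_vars(lp, work, split=True)
    _build_stoich_rows(lp, work, var_of)
    slack = 1e-9 * max(1.0, abs(target))
    lp.add_constraint(
        {j: s for j, s in var_of[objective].items()},
        target - slack, DEFAULT_BOUND)
    lp.set_objective({j: 1.0 for v in var_of.values() for j in v}, sense="min")
    status, _, x = lp.solve()
    if status != OPTIMAL:
        return FluxSolution(status)
    fluxes = _extract_fluxes(work, var_of, x)
    return FluxSolution(OPTIMAL, fluxes[objective], fluxes)


def fva(model: MetabolicModel, medium: Medium | None,
        objective: str | None = None, optimum_fraction: float = 1.0,
        reactions: list[str] | None = None) -> dict[str, tuple[float, float]]:
    """Per-reaction flux range with the objective held at (a fraction of)
    its optimum."""
    objective = objective or model.objective_id
    first = fba(model, medium, objective)
    if not first.ok:
        raise SolverError(f"FBA {first.status}; FVA undefined")
    target = optimum_fraction * first.objective
    work = model.copy()
    if medium is not None:
        apply_medium(work, medium)
    wanted = sorted(reactions) if reactions is not None else sorted(work.reactions)
    out: dict[str, tuple[float, float]] = {}
    slack = 1e-9 * max(1.0, abs(target))
    for rid in wanted:
        lohi = []
        for sense in ("min", "max"):
            lp = LinearProgram()
            var_of = _make_flux_vars(lp, work, split=False)
            _build_stoich_rows(lp, work, var_of)
            (j_obj,) = var_of[objective]
            lp.add_constraint({j_obj: 1.0}, target - slack, DEFAULT_BOUND)
            (j_r,) = var_of[rid]
            lp.set_objective({j_r: 1.0}, sense=sense)
            status, val, _ = lp.solve()
            if status != OPTIMAL:
                raise SolverError(f"FVA {sense} for {rid}: {status}")
            lohi.append(val)
        out[rid] = (lohi[0], lohi[1])
    return out


def evidence_weight(bitscore: float | None, in_draft: bool,
                    params: GapfillParams | None = None) -> float:
    """Piecewise bitscore→weight mapping of the gap-filling objective.

    w_min for draft reactions or b ≥ u; w_max for b < l (or no evidence);
    linear in between. Continuous at both break points.
    """
    p = params or GapfillParams()
    if in_draft:
        return p.w_min
    if bitscore is None or bitscore < p.l:
        return p.w_max
    if bitscore >= p.u:
        return p.w_min
    return (bitscore - p.u) * ((p.w_min - p.w_max) / (p.u - p.l)) + p.w_min


def weighted_gapfill_lp(
    universal: MetabolicModel,
    draft_ids: set[str],
    bitscores: dict[str, float],
    objective: str,
    medium: Medium | None,
    params: GapfillParams | None = None,
    candidate_ids: set[str] | None = None,
) -> tuple[FluxSolution, list[str]]:
    """Solve the evidence-weighted gap-filling LP on the universal model.

    Parameters
    ----------
    universal:
        Reaction source; must contain the draft reactions, the objective
        and every exchange the medium refers to.
    draft_ids:
        Reactions already in the draft (weight w_min, never "added").
    bitscores:
        Best supporting bitscore per reaction id; absent ⇒ w_max.
    candidate_ids:
        If given, non-draft reactions outside this set are shut off
        (bounds 0) — used by the core-restricted protocol steps.

    Returns the LP solution and the non-draft reactions carrying flux
    above the tolerance, in lexicographic id order.
    """
    p = params or GapfillParams()
    if objective not in universal.reactions:
        raise ValueError(f"objective reaction {objective!r} not in universal model")
    work = universal.copy()
    if medium is not None:
        apply_medium(work, medium)
    if candidate_ids is not None:
        for rid, rxn in work.reactions.items():
            if rid not in draft_ids and rid != objective and rid not in candidate_ids:
                rxn.lb = rxn.ub = 0.0
    lp = LinearProgram()
    var_of = _make_flux_vars(lp, work, split=True)
    _build_stoich_rows(lp, work, var_of)
    obj: dict[int, float] = {}
    from .biochem import is_exchange  # local to avoid cycle at import time
    for rid in sorted(work.reactions):
        if p.exempt_exchanges and is_exchange(work.reactions[rid]):
            w = 0.0
        else:
            w = evidence_weight(bitscores.get(rid), rid in draft_ids, p)
        for j in var_of[rid]:
            obj[j] = obj.get(j, 0.0) - p.c * w
    for j, s in var_of[objective].items():
        obj[j] = obj.get(j, 0.0) + s
    lp.set_objective(obj, sense="max")
    status, objval, x = lp.solve()
    if status != OPTIMAL:
        raise SolverError(
            f"gap-filling LP {status}: objective {objective!r} unreachable "
            "even in the universal model")
    fluxes = _extract_fluxes(work, var_of, x)
    added = [rid for rid in sorted(work.reactions)
             if rid not in draft_ids and abs(fluxes[rid]) > p.flux_tolerance]
    return FluxSolution(OPTIMAL, objval, fluxes), added
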