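"""Phenotype prediction on finished models: carbon-source utilisation,
fermentation products, gene essentiality, GPR logic.

Carbon-source tests emulate colorimetric utilisation assays: three
temporary reactions recycle the reduced electron carriers (menaquinol,
quinol, NADH); a substance is called an energy source when, on a minimal
medium with that substance, the summed recycling flux can be positive.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import pandas as pd

from .biochem import CYTOSOL, Metabolite, Reaction
from .lp import SolverError, fba, fva, mtf
from .model import MetabolicModel, Medium

#: electron-carrier couples recycled by the utilisation assay:
#: (temporary reaction id, reduced form, oxidised form, protons released)
ESP_COUPLES = (
    ("ESP1", f"mql8_{CYTOSOL}", f"mqn8_{CYTOSOL}", 2),
    ("ESP2", f"q8h2_{CYTOSOL}", f"q8_{CYTOSOL}", 2),
    ("ESP3", f"nadh_{CYTOSOL}", f"nad_{CYTOSOL}", 1),
)
ESP_POOL = f"esp_pool_{CYTOSOL}"
ESP_DRAIN = "ESP_DRAIN"


def add_esp_reactions(model: MetabolicModel,
                      couples=ESP_COUPLES) -> list[str]:
    """Insert the recycling trio plus a drain whose flux equals their
    sum (in place). Couples whose carriers are absent from the model are
    skipped. Returns the inserted reaction ids, drain last."""
    model.metabolites[ESP_POOL] = Metabolite(
        id=ESP_POOL, name="electron-recycling indicator (pseudo)",
        formula=None, charge=None, compartment=CYTOSOL)
    h = f"h_{CYTOSOL}"
    ids = []
    for rid, reduced, oxidised, protons in couples:
        if reduced not in model.metabolites or oxidised not in model.metabolites:
            continue
        stoich = {reduced: -1.0, oxidised: 1.0, ESP_POOL: 1.0}
        stoich[h] = stoich.get(h, 0.0) + protons
        model.add_reaction(Reaction(
            id=rid, name=f"temporary recycling of {reduced}",
            stoichiometry=stoich, reversibility=">"))
        ids.append(rid)
    model.add_reaction(Reaction(
        id=ESP_DRAIN, name="recycling indicator drain",
        stoichiometry={ESP_POOL: -1.0}, reversibility=">"))
    ids.append(ESP_DRAIN)
    return ids


def remove_esp_reactions(model: MetabolicModel) -> None:
    for rid, *_ in ESP_COUPLES:
        model.reactions.pop(rid, None)
    model.reactions.pop(ESP_DRAIN, None)
    model.metabolites.pop(ESP_POOL, None)


def test_carbon_source(model: MetabolicModel, minimal_medium: Medium,
                       substance_e_met: str, uptake_rate: float = 10.0,
                       tolerance: float = 1e-6) -> tuple[bool, float]:
    """Can *substance_e_met* serve as an energy source?

    The input model is never modified (the assay runs on a copy, so the
    temporary recycling reactions cannot leak out).
    """
    ex_id = f"EX_{substance_e_met}"
    if ex_id not in model.reactions:
        raise ValueError(f"no exchange reaction for {substance_e_met!r}")
    work = model.copy()
    add_esp_reactions(work)
    medium = minimal_medium.with_compound(substance_e_met, uptake_rate)
    sol = fba(work, medium, ESP_DRAIN)
    if not sol.ok:
        raise SolverError(f"carbon-source FBA {sol.status}")
    return sol.objective > tolerance, sol.objective


@dataclass
class FermentationProfile:
    growth_rate: float                       # h⁻¹
    #: exchange metabolite → release normalized by growth (mmol/gDW)
    mtf_release: dict[str, float] = field(default_factory=dict)
    fva_max_release: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "metabolite": m,
            "mtf_release_mmol_per_gDW": self.mtf_release[m],
            "fva_max_mmol_per_gDW": self.fva_max_release.get(m, float("nan")),
            "growth_h_1": self.growth_rate,
        } for m in sorted(self.mtf_release)])


def predict_fermentation_products(model: MetabolicModel, medium: Medium,
                                  tolerance: float = 1e-6) -> FermentationProfile:
    """By-product release under the given (typically anaerobic) medium.

    Flux balance with minimal total flux gives the parsimonious release
    per product; flux variability at the growth optimum gives the
    maximum possible release. Both are normalized by the growth rate, so
    values are mmol per gram dry weight of biomass formed.
    """
    sol = mtf(model, medium)
    if not sol.ok:
        raise SolverError(f"growth FBA {sol.status}")
    growth = sol.objective
    if growth < tolerance:
        raise ValueError("no growth on this medium; normalization undefined")
    products = {}
    for ex_id in model.exchanges:
        flux = sol.fluxes.get(ex_id, 0.0)
        if flux > tolerance:
            met = next(iter(model.reactions[ex_id].stoichiometry))
            products[met] = flux / growth
    ranges = fva(model, medium, optimum_fraction=1.0,
                 reactions=[f"EX_{m}" for m in products])
    fva_max = {m: ranges[f"EX_{m}"][1] / growth for m in products}
    return FermentationProfile(growth, products, fva_max)


# --- GPR logic -------------------------------------------------------------

class GprParseError(ValueError):
    pass


_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(expr: str) -> list[tuple[str, int]]:
    return [(m.group(0), m.start()) for m in _TOKEN.finditer(expr)]


class _GprParser:
    """Recursive-descent parser for boolean gene expressions:
    expr := term ('or' term)*; term := factor ('and' factor)*;
    factor := '(' expr ')' | gene."""

    def __init__(self, expr: str):
        self.expr = expr
        self.tokens = _tokenize(expr)
        self.pos = 0

    def _peek(self):
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def _error(self, msg):
        at = (self.tokens[self.pos][1] if self.pos < len(self.tokens)
              else len(self.expr))
        raise GprParseError(f"{msg} at position {at} in {self.expr!r}")

    def parse(self):
        node = self._expr()
        if self._peek() is not None:
            self._error("unexpected token")
        return node

    def _expr(self):
        terms = [self._term()]
        while self._peek() is not None and self._peek().lower() == "or":
            self.pos += 1
            terms.append(self._term())
        return ("or", terms) if len(terms) > 1 else terms[0]

    def _term(self):
        factors = [self._factor()]
        while self._peek() is not None and self._peek().lower() == "and":
            self.pos += 1
            factors.append(self._factor())
        return ("and", factors) if len(factors) > 1 else factors[0]

    def _factor(self):
        tok = self._peek()
        if tok is None:
            self._error("unexpected end of expression")
        if tok == "(":
            self.pos += 1
            node = self._expr()
            if self._peek() != ")":
                self._error("expected ')'")
            self.pos += 1
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            self._error(f"unexpected {tok!r}")
        self.pos += 1
        return ("gene", tok)


def parse_gpr(gpr: str):
    return _GprParser(gpr).parse()


def gpr_genes(gpr: str) -> set[str]:
    if not gpr.strip():
        return set()

    def walk(node, acc):
        if node[0] == "gene":
            acc.add(node[1])
        else:
            for child in node[1]:
                walk(child, acc)
    acc: set[str] = set()
    walk(parse_gpr(gpr), acc)
    return acc


def evaluate_gpr(gpr: str, deleted_genes: set[str] | frozenset = frozenset()) -> bool:
    """Boolean value of a GPR with the deleted genes false and all other
    genes true. An empty GPR means the reaction is not gene-controlled
    and evaluates true."""
    if not gpr.strip():
        return True

    def ev(node):
        kind = node[0]
        if kind == "gene":
            return node[1] not in deleted_genes
        values = (ev(child) for child in node[1])
        return all(values) if kind == "and" else any(values)
    return ev(parse_gpr(gpr))


def gpr_equivalence(gpr_a: str, gpr_b: str, max_genes: int = 20) -> bool:
    """Truth-table equivalence over the union of the two gene sets."""
    genes = sorted(gpr_genes(gpr_a) | gpr_genes(gpr_b))
    if len(genes) > max_genes:
        raise ValueError(
            f"{len(genes)} distinct genes exceed the combinatorial limit "
            f"of {max_genes}")
    for pattern in itertools.product((False, True), repeat=len(genes)):
        deleted = {g for g, present in zip(genes, pattern) if not present}
        if evaluate_gpr(gpr_a, deleted) != evaluate_gpr(gpr_b, deleted):
            return False
    return True


def single_gene_deletions(model: MetabolicModel, medium: Medium,
                          growth_threshold: float = 0.01
                          ) -> dict[str, tuple[float, bool]]:
    """In-silico single-knockout screen.

    Per gene: every reaction whose GPR evaluates false under the
    deletion is disabled (bounds 0), growth is recomputed by FBA, and
    the gene is called conditionally essential when growth falls below
    the threshold (default 0.01 h⁻¹).
    """
    results: dict[str, tuple[float, bool]] = {}
    gene_rxns: dict[str, list[str]] = {}
    for rid, rxn in model.reactions.items():
        for g in gpr_genes(rxn.gpr):
            gene_rxns.setdefault(g, []).append(rid)
    for gene in sorted(gene_rxns):
        work = model.copy()
        deleted = {gene}
        for rid in gene_rxns[gene]:
            if not evaluate_gpr(work.reactions[rid].gpr, deleted):
                work.reactions[rid].lb = work.reactions[rid].ub = 0.0
        sol = fba(work, medium)
        growth = sol.objective if sol.ok else 0.0
        results[gene] = (growth, growth < growth_threshold)
    return results


def save_essentiality(results: dict[str, tuple[float, bool]], path) -> None:
    pd.DataFrame([{"gene": g, "growth": round(v[0], 6), "essential": int(v[1])}
                  for g, v in sorted(results.items())]).to_csv(
        path, sep="\t", index=False)


def contingency_metrics(predicted: dict[str, bool],
                        observed: dict[str, bool]) -> dict[str, float]:
    """TP/FP/TN/FN and derived rates over the shared keys."""
    keys = sorted(set(predicted) & set(observed))
    tp = sum(1 for k in keys if predicted[k] and observed[k])
    fp = sum(1 for k in keys if predicted[k] and not observed[k])
    tn = sum(1 for k in keys if not predicted[k] and not observed[k])
    fn = sum(1 for k in keys if not predicted[k] and observed[k])
    out = {"tp": tp, "fp": fp, "tn": tn, "fn": fn}
    out["sensitivity"] = tp / (tp + fn) if tp + fn else float("nan")
    out["specificity"] = tn / (tn + fp) if tn + fp else float("nan")
    out["accuracy"] = (tp + tn) / len(keys) if keys else float("nan")
    return out
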