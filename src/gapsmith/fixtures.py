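"""Deterministic synthetic test world: a small, mass- and charge-balanced
biochemistry database with glycolysis, TCA cycle, respiration, and mixed-
acid fermentation branches, plus pathway definitions, reference-header
sets for protein complexes, transporter evidence, growth media, and
per-organism homology hit tables with planted ground truth.

Everything every other module consumes can be generated from here, so the
full pipeline is testable without any external downloads. The chemistry
uses real small-molecule formulas where convenient (so the balance
validators have teeth) and synthetic but balanced species elsewhere
(``murX``, ``taX``, ``lpsX`` — cell-envelope analogues).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .biochem import (
    CYTOSOL,
    EXTRACELLULAR,
    Metabolite,
    Reaction,
    ReactionDatabase,
    parse_formula,
    save_reaction_db,
)
from .complexes import SubunitCatalog, parse_subunits
from .draft import BiomassTemplate, save_biomass_templates
from .evidence import HomologyHit, save_hit_table
from .model import Medium, save_medium
from .pathways import PathwayDef, PathwayEntry, save_pathway_db
from .transporters import SubstanceMap, save_substance_map

# --- metabolite catalogue: base id → (name, formula, charge) ---------------

_MET_INFO: dict[str, tuple[str, str, int]] = {
    "glc__D": ("D-glucose", "C6H12O6", 0),
    "fru": ("D-fructose", "C6H12O6", 0),
    "g6p": ("glucose 6-phosphate", "C6H11O9P", -2),
    "f6p": ("fructose 6-phosphate", "C6H11O9P", -2),
    "fdp": ("fructose 1,6-bisphosphate", "C6H10O12P2", -4),
    "dhap": ("dihydroxyacetone phosphate", "C3H5O6P", -2),
    "g3p": ("glyceraldehyde 3-phosphate", "C3H5O6P", -2),
    "13dpg": ("1,3-bisphosphoglycerate", "C3H4O10P2", -4),
    "3pg": ("3-phosphoglycerate", "C3H4O7P", -3),
    "2pg": ("2-phosphoglycerate", "C3H4O7P", -3),
    "pep": ("phosphoenolpyruvate", "C3H2O6P", -3),
    "pyr": ("pyruvate", "C3H3O3", -1),
    "lac__D": ("D-lactate", "C3H5O3", -1),
    "for": ("formate", "CHO2", -1),
    "ac": ("acetate", "C2H3O2", -1),
    "actp": ("acetyl phosphate", "C2H3O5P", -2),
    "acald": ("acetaldehyde", "C2H4O", 0),
    "etoh": ("ethanol", "C2H6O", 0),
    "accoa": ("acetyl-CoA", "C23H34N7O17P3S", -4),
    "coa": ("coenzyme A", "C21H32N7O16P3S", -4),
    "cit": ("citrate", "C6H5O7", -3),
    "icit": ("isocitrate", "C6H5O7", -3),
    "akg": ("2-oxoglutarate", "C5H4O5", -2),
    "succoa": ("succinyl-CoA", "C25H35N7O19P3S", -5),
    "succ": ("succinate", "C4H4O4", -2),
    "fum": ("fumarate", "C4H2O4", -2),
    "mal__L": ("L-malate", "C4H4O5", -2),
    "oaa": ("oxaloacetate", "C4H2O5", -2),
    "r5p": ("ribose 5-phosphate", "C5H9O8P", -2),
    "ala__L": ("L-alanine", "C3H7NO2", 0),
    "glu__L": ("L-glutamate", "C5H8NO4", -1),
    "hdca": ("hexadecanoate", "C16H31O2", -1),
    "atp": ("ATP", "C10H12N5O13P3", -4),
    "adp": ("ADP", "C10H12N5O10P2", -3),
    "pi": ("phosphate", "HO4P", -2),
    "h": ("proton", "H", 1),
    "h2o": ("water", "H2O", 0),
    "nad": ("NAD+", "C21H26N7O14P2", -1),
    "nadh": ("NADH", "C21H27N7O14P2", -2),
    "q8": ("ubiquinone-8", "C49H74O4", 0),
    "q8h2": ("ubiquinol-8", "C49H76O4", 0),
    "mqn8": ("menaquinone-8", "C51H72O2", 0),
    "mql8": ("menaquinol-8", "C51H74O2", 0),
    "o2": ("oxygen", "O2", 0),
    "co2": ("carbon dioxide", "CO2", 0),
    "hco3": ("bicarbonate", "CHO3", -1),
    "nh3": ("ammonia", "H3N", 0),
    "h2": ("hydrogen", "H2", 0),
    "murX": ("cell-wall unit (synthetic)", "C8H15NO6", 0),
    "taX": ("teichoic-acid analogue (synthetic)", "C6H12O13P2", -4),
    "lpsX": ("lipopolysaccharide analogue (synthetic)", "C22H41O14P2", -5),
}

#: compounds with both cytosolic and extracellular species
_EXTRACELLULAR_BASES = ("glc__D", "fru", "lac__D", "ac", "etoh", "pi", "h",
                        "nh3", "h2o", "o2", "co2", "h2", "ala__L", "hdca")

DIFFUSION_COMPOUNDS = ("h2", "o2", "co2", "h2o", "nh3")


def _c(base):
    return f"{base}_{CYTOSOL}"


def _e(base):
    return f"{base}_{EXTRACELLULAR}"


# --- reaction catalogue ----------------------------------------------------
# (id, name, stoichiometry over base ids (cytosol unless suffixed),
#  reversibility, ec, is_transport, is_spontaneous)

def _reaction_defs():
    c, e = _c, _e
    R = []

    def add(rid, name, stoich, rev, ec="", transport=False, spont=False):
        R.append((rid, name, stoich, rev, ec, transport, spont))

    # glycolysis
    add("PGI", "glucose-6-phosphate isomerase",
        {c("g6p"): -1, c("f6p"): 1}, "=", "5.3.1.9")
    add("PFK", "phosphofructokinase",
        {c("f6p"): -1, c("atp"): -1, c("fdp"): 1, c("adp"): 1, c("h"): 1},
        ">", "2.7.1.11")
    add("FBA", "fructose-bisphosphate aldolase",
        {c("fdp"): -1, c("dhap"): 1, c("g3p"): 1}, "=", "4.1.2.13")
    add("TPI", "triose-phosphate isomerase",
        {c("dhap"): -1, c("g3p"): 1}, "=", "5.3.1.1")
    add("GAPD", "glyceraldehyde-3-phosphate dehydrogenase",
        {c("g3p"): -1, c("nad"): -1, c("pi"): -1,
         c("13dpg"): 1, c("nadh"): 1, c("h"): 1}, "=", "1.2.1.12")
    add("PGK", "phosphoglycerate kinase",
        {c("13dpg"): -1, c("adp"): -1, c("3pg"): 1, c("atp"): 1}, "=", "2.7.2.3")
    add("PGM", "phosphoglycerate mutase",
        {c("3pg"): -1, c("2pg"): 1}, "=", "5.4.2.11")
    add("ENO", "enolase", {c("2pg"): -1, c("pep"): 1, c("h2o"): 1}, "=", "4.2.1.11")
    add("PYK", "pyruvate kinase",
        {c("pep"): -1, c("adp"): -1, c("h"): -1, c("pyr"): 1, c("atp"): 1},
        ">", "2.7.1.40")
    # fructose entry
    add("FRK", "fructokinase",
        {c("fru"): -1, c("atp"): -1, c("f6p"): 1, c("adp"): 1, c("h"): 1},
        ">", "2.7.1.4")
    # pentose shunt (lumped, oxidative)
    add("PPPS", "pentose-phosphate shunt (lumped)",
        {c("g6p"): -1, c("nad"): -2, c("h2o"): -1,
         c("r5p"): 1, c("co2"): 1, c("nadh"): 2, c("h"): 2}, ">", "1.1.1.49")
    # pyruvate branches
    add("LDH_D", "D-lactate dehydrogenase",
        {c("pyr"): -1, c("nadh"): -1, c("h"): -1, c("lac__D"): 1, c("nad"): 1},
        ">", "1.1.1.28")
    add("PDH", "pyruvate dehydrogenase",
        {c("pyr"): -1, c("coa"): -1, c("nad"): -1,
         c("accoa"): 1, c("co2"): 1, c("nadh"): 1}, ">", "1.2.4.1")
    add("PFL", "pyruvate formate-lyase",
        {c("pyr"): -1, c("coa"): -1, c("accoa"): 1, c("for"): 1}, ">", "2.3.1.54")
    add("FHL", "formate hydrogen-lyase",
        {c("for"): -1, c("h"): -1, c("co2"): 1, c("h2"): 1}, ">", "1.17.98.4")
    add("PTAr", "phosphotransacetylase",
        {c("accoa"): -1, c("pi"): -1, c("actp"): 1, c("coa"): 1}, "=", "2.3.1.8")
    add("ACKr", "acetate kinase",
        {c("actp"): -1, c("adp"): -1, c("ac"): 1, c("atp"): 1}, "=", "2.7.2.1")
    add("ACALD", "acetaldehyde dehydrogenase (acylating)",
        {c("acald"): -1, c("coa"): -1, c("nad"): -1,
         c("accoa"): 1, c("nadh"): 1, c("h"): 1}, "=", "1.2.1.10")
    add("ALCD2x", "alcohol dehydrogenase",
        {c("etoh"): -1, c("nad"): -1, c("acald"): 1, c("nadh"): 1, c("h"): 1},
        "=", "1.1.1.1")
    # TCA cycle
    add("CS", "citrate synthase",
        {c("accoa"): -1, c("h2o"): -1, c("oaa"): -1,
         c("cit"): 1, c("coa"): 1, c("h"): 1}, ">", "2.3.3.1")
    add("ACONT", "aconitase", {c("cit"): -1, c("icit"): 1}, "=", "4.2.1.3")
    add("ICDHx", "isocitrate dehydrogenase (NAD)",
        {c("icit"): -1, c("nad"): -1, c("akg"): 1, c("co2"): 1, c("nadh"): 1},
        ">", "1.1.1.41")
    add("AKGDH", "2-oxoglutarate dehydrogenase",
        {c("akg"): -1, c("coa"): -1, c("nad"): -1,
         c("succoa"): 1, c("co2"): 1, c("nadh"): 1}, ">", "1.2.4.2")
    add("SUCOAS", "succinyl-CoA synthetase",
        {c("succoa"): -1, c("adp"): -1, c("pi"): -1,
         c("succ"): 1, c("atp"): 1, c("coa"): 1}, "=", "6.2.1.5")
    add("SUCDi", "succinate dehydrogenase",
        {c("succ"): -1, c("q8"): -1, c("fum"): 1, c("q8h2"): 1}, ">", "1.3.5.1")
    add("FUM", "fumarase", {c("fum"): -1, c("h2o"): -1, c("mal__L"): 1},
        "=", "4.2.1.2")
    add("MDH", "malate dehydrogenase",
        {c("mal__L"): -1, c("nad"): -1, c("oaa"): 1, c("nadh"): 1, c("h"): 1},
        "=", "1.1.1.37")
    # anaplerosis + spontaneous CO2 hydration
    add("HCO3E", "carbonate equilibration",
        {c("co2"): -1, c("h2o"): -1, c("h"): 1, c("hco3"): 1},
        "=", "", spont=True)
    add("PPC", "phosphoenolpyruvate carboxylase",
        {c("pep"): -1, c("hco3"): -1, c("oaa"): 1, c("pi"): 1}, ">", "4.1.1.31")
    # respiration / energy
    add("NADH16", "NADH dehydrogenase (ubiquinone, proton-pumping)",
        {c("nadh"): -1, c("h"): -5, c("q8"): -1,
         c("nad"): 1, c("q8h2"): 1, e("h"): 4}, ">", "7.1.1.2")
    add("MQNDH", "NADH dehydrogenase (menaquinone)",
        {c("nadh"): -1, c("h"): -1, c("mqn8"): -1, c("nad"): 1, c("mql8"): 1},
        ">", "1.6.5.11")
    add("FRD", "fumarate reductase (menaquinol)",
        {c("fum"): -1, c("mql8"): -1, c("succ"): 1, c("mqn8"): 1}, ">", "1.3.5.4")
    add("CYTBO3", "cytochrome oxidase bo3 (proton-pumping)",
        {c("q8h2"): -1, c("o2"): -0.5, c("h"): -2,
         c("q8"): 1, c("h2o"): 1, e("h"): 2}, ">", "7.1.1.3")
    add("ATPS4r", "ATP synthase (F1F0)",
        {c("adp"): -1, c("pi"): -1, e("h"): -4,
         c("atp"): 1, c("h2o"): 1, c("h"): 3}, "=", "7.1.2.2")
    add("ATPM", "ATP maintenance/dissipation",
        {c("atp"): -1, c("h2o"): -1, c("adp"): 1, c("pi"): 1, c("h"): 1},
        ">", "3.6.1.3")
    # biosynthesis
    add("ALAD", "alanine dehydrogenase",
        {c("pyr"): -1, c("nh3"): -1, c("nadh"): -1, c("h"): -2,
         c("ala__L"): 1, c("nad"): 1, c("h2o"): 1}, ">", "1.4.1.1")
    add("GLUDy", "glutamate dehydrogenase",
        {c("akg"): -1, c("nh3"): -1, c("nadh"): -1, c("h"): -2,
         c("glu__L"): 1, c("nad"): 1, c("h2o"): 1}, ">", "1.4.1.4")
    add("FAS_toy", "fatty-acid synthesis (lumped)",
        {c("accoa"): -8, c("nadh"): -14, c("h"): -13,
         c("hdca"): 1, c("coa"): 8, c("nad"): 14, c("h2o"): 6}, ">", "2.3.1.85")
    add("MURS_toy", "cell-wall unit synthesis (lumped)",
        {c("f6p"): -1, c("nh3"): -1, c("accoa"): -1,
         c("murX"): 1, c("coa"): 1, c("pi"): 1}, ">", "2.6.1.16")
    add("TAS_toy", "teichoic-acid analogue synthesis (lumped)",
        {c("g6p"): -1, c("atp"): -1, c("h2o"): -1,
         c("taX"): 1, c("adp"): 1, c("h"): 1}, ">", "2.7.8.12")
    add("LPSS_toy", "lipopolysaccharide analogue synthesis (lumped)",
        {c("g6p"): -1, c("hdca"): -1, c("atp"): -1,
         c("lpsX"): 1, c("adp"): 1, c("h"): 1}, ">", "2.4.1.182")
    # transporters
    add("GLCpts", "D-glucose transport via PEP:Pyr PTS",
        {e("glc__D"): -1, c("pep"): -1, c("g6p"): 1, c("pyr"): 1},
        ">", "2.7.1.199", transport=True)
    add("FRUabc", "D-fructose transport via ABC system",
        {e("fru"): -1, c("atp"): -1, c("h2o"): -1,
         c("fru"): 1, c("adp"): 1, c("pi"): 1, c("h"): 1},
        ">", "7.5.2.1", transport=True)
    add("LACt2r", "D-lactate transport via proton symport",
        {e("lac__D"): -1, e("h"): -1, c("lac__D"): 1, c("h"): 1},
        "=", "", transport=True)
    add("ACt2r", "acetate transport via proton symport",
        {e("ac"): -1, e("h"): -1, c("ac"): 1, c("h"): 1},
        "=", "", transport=True)
    add("ETOHt", "ethanol transport via channel",
        {e("etoh"): -1, c("etoh"): 1}, "=", "", transport=True)
    add("PIt2r", "phosphate transport via proton symport",
        {e("pi"): -1, e("h"): -1, c("pi"): 1, c("h"): 1},
        "=", "", transport=True)
    add("ALAt2r", "L-alanine transport via proton symport",
        {e("ala__L"): -1, e("h"): -1, c("ala__L"): 1, c("h"): 1},
        "=", "", transport=True)
    add("HDCAt2r", "hexadecanoate transport via proton symport",
        {e("hdca"): -1, e("h"): -1, c("hdca"): 1, c("h"): 1},
        "=", "", transport=True)
    return R


#: reactions whose best evidence is planted below the direct-inclusion
#: cutoff for the "fermenter" organism (bitscore values are the plant)
FERMENTER_WEAK = {"LDH_D": 140.0, "FRK": 130.0, "FRUabc": 130.0}
AUXOTROPH_WEAK = {"ALAD": 120.0, "FAS_toy": 20.0}
SINGLE_GAP_REACTION = "PPC"

COMPLEX_REACTIONS = ("GLCpts", "ATPS4r")
ISOZYME_REACTIONS = ("ACKr",)

#: reactions without reference sequences (vague in pathway definitions);
#: organisms never receive direct hits for them
NO_REFERENCE_REACTIONS = ("ACt2r",)

ENERGY_DISSIPATION_ID = "ATPM"


def _complex_headers() -> dict[str, list[str]]:
    return {
        "GLCpts": (
            [f"ref|pts{i}| PTS glucose transporter subunit I" for i in range(6)]
            + [f"ref|ptsH{i}| PTS glucose transporter subunit II" for i in range(5)]
            + [f"ref|ptsC{i}| PTS system component III" for i in range(3)]
            + [f"ref|ptsU{i}| hypothetical protein" for i in range(2)]
        ),
        "ATPS4r": (
            [f"ref|atpA{i}| ATP synthase subunit alpha" for i in range(7)]
            + [f"ref|atpB{i}| ATP synthase subunit beta" for i in range(6)]
            + ["ref|atpG0| ATP synthase chain gamma"]
        ),
    }


def _substance_map() -> SubstanceMap:
    sm = SubstanceMap()
    pairs = {
        "glucose": ("", _e("glc__D")),
        "fructose": (_c("fru"), _e("fru")),
        "lactate": (_c("lac__D"), _e("lac__D")),
        "acetate": (_c("ac"), _e("ac")),
        "ethanol": (_c("etoh"), _e("etoh")),
        "alanine": (_c("ala__L"), _e("ala__L")),
        "palmitate": (_c("hdca"), _e("hdca")),
        "phosphate": (_c("pi"), _e("pi")),
    }
    sm.compounds.update(pairs)
    sm.synonyms.update({
        "d-glucose": "glucose", "d-fructose": "fructose",
        "d-lactate": "lactate", "hexadecanoate": "palmitate",
    })
    return sm


#: substances probed by the energy-source and product gap-filling steps
TEST_SUBSTANCES = ("glucose", "fructose", "lactate", "acetate", "ethanol",
                   "alanine", "palmitate")


def _pathway_defs() -> list[PathwayDef]:
    def E(rid, key=False, spont=False, has_seq=True):
        return PathwayEntry(rid, key=key, spontaneous=spont,
                            has_reference_sequences=has_seq)

    return [
        PathwayDef("PWY_GLYCOLYSIS", "glycolysis", (
            E("PGI"), E("PFK", key=True), E("FBA"), E("TPI"), E("GAPD"),
            E("PGK"), E("PGM"), E("ENO"), E("PYK", key=True))),
        PathwayDef("PWY_TCA", "TCA cycle", (
            E("CS", key=True), E("ACONT"), E("ICDHx"), E("AKGDH"),
            E("SUCOAS"), E("SUCDi"), E("FUM"), E("MDH"))),
        PathwayDef("PWY_FERM_LAC", "lactate fermentation", (
            E("LDH_D"), E("LACt2r"))),
        PathwayDef("PWY_FERM_ETOH", "ethanol fermentation", (
            E("ALCD2x"), E("ACALD"), E("ETOHt"))),
        PathwayDef("PWY_ACETATE", "acetate fermentation", (
            E("PTAr", key=True), E("ACKr"), E("ACt2r", has_seq=False))),
        PathwayDef("PWY_FRUCTOSE", "fructose utilisation", (
            E("FRUabc"), E("FRK"))),
        PathwayDef("PWY_AA", "amino-acid synthesis", (
            E("ALAD"), E("GLUDy"))),
        PathwayDef("PWY_ANAPLEROSIS", "anaplerosis", (
            E("PPC", key=True), E("HCO3E", spont=True))),
    ]


def _biomass_templates() -> dict[str, BiomassTemplate]:
    common = {
        _c("ala__L"): 0.5, _c("glu__L"): 0.2, _c("r5p"): 0.15,
        _c("g6p"): 0.2, _c("hdca"): 0.05, _c("murX"): 0.1,
    }
    neg = dict(common)
    neg[_c("lpsX")] = 0.05
    pos = dict(common)
    pos[_c("taX")] = 0.08
    return {
        "negative": BiomassTemplate("negative", neg, energy_atp=40.0),
        "positive": BiomassTemplate("positive", pos, energy_atp=40.0),
    }


def _media() -> dict[str, Medium]:
    m9_base = {
        _e("o2"): 20.0, _e("nh3"): 100.0, _e("pi"): 100.0,
        _e("h2o"): 100.0, _e("h"): 100.0, _e("co2"): 100.0,
    }
    m9_glc = dict(m9_base)
    m9_glc[_e("glc__D")] = 10.0
    anaerobic = {k: v for k, v in m9_glc.items() if k != _e("o2")}
    return {
        "complete": Medium({}, name="complete", default_rate=100.0),
        "m9_base": Medium(m9_base, name="m9_base"),
        "m9_glc": Medium(m9_glc, name="m9_glc"),
        "m9_glc_anaerobic": Medium(anaerobic, name="m9_glc_anaerobic"),
    }


@dataclass
class ToyWorld:
    db: ReactionDatabase
    pathway_defs: list[PathwayDef]
    substance_map: SubstanceMap
    biomass_templates: dict[str, BiomassTemplate]
    media: dict[str, Medium]
    complex_headers: dict[str, list[str]]
    catalogs: dict[str, SubunitCatalog]
    substances: tuple[str, ...] = TEST_SUBSTANCES
    diffusion_compounds: tuple[str, ...] = DIFFUSION_COMPOUNDS
    energy_dissipation_id: str = ENERGY_DISSIPATION_ID

    def write(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        save_reaction_db(self.db, d / "reactions.tsv", d / "metabolites.tsv")
        save_pathway_db(self.pathway_defs, d / "pathways.tsv")
        save_substance_map(self.substance_map, d / "substances.tsv")
        save_biomass_templates(self.biomass_templates, d / "biomass.tsv")
        for name, medium in self.media.items():
            save_medium(medium, d / f"medium_{name}.csv")
        with open(d / "complex_refs.fasta", "w") as fh:
            for rid in sorted(self.complex_headers):
                for header in self.complex_headers[rid]:
                    fh.write(f">{rid}|{header}\nM\n")


def make_toy_world(seed: int = 0) -> ToyWorld:
    """Build the toy world. The content is fully deterministic; the seed
    is accepted for interface symmetry with the organism generator."""
    db = ReactionDatabase()
    used: set[str] = set()
    defs = _reaction_defs()
    for _, _, stoich, *_ in defs:
        used |= set(stoich)
    for base in _EXTRACELLULAR_BASES:
        used.add(_e(base))
    for t in _biomass_templates().values():
        used |= set(t.components)
    for mid in sorted(used):
        base, comp = mid.rsplit("_", 1)
        name, formula, charge = _MET_INFO[base]
        db.add_metabolite(Metabolite(
            id=mid, name=name, formula=parse_formula(formula),
            charge=charge, compartment=comp))
    for rid, name, stoich, rev, ec, transport, spont in defs:
        db.add_reaction(Reaction(
            id=rid, name=name, stoichiometry=dict(stoich), reversibility=rev,
            ec_numbers=(ec,) if ec else (), is_transport=transport,
            is_spontaneous=spont))
    db.validate()
    headers = _complex_headers()
    catalogs = {rid: parse_subunits(hdrs, rid) for rid, hdrs in headers.items()}
    return ToyWorld(
        db=db,
        pathway_defs=_pathway_defs(),
        substance_map=_substance_map(),
        biomass_templates=_biomass_templates(),
        media=_media(),
        complex_headers=headers,
        catalogs=catalogs,
    )


def make_corrupted_db(world: ToyWorld) -> ReactionDatabase:
    """World database plus a mis-annotated ATP synthase copy whose proton
    accounting nets out — a planted energy-generating cycle."""
    db = ReactionDatabase(
        metabolites=dict(world.db.metabolites),
        reactions={rid: r.copy() for rid, r in world.db.reactions.items()},
        compartments=world.db.compartments)
    db.add_reaction(Reaction(
        id="ATPS4r_misannotated",
        name="ATP synthase (mis-annotated copy)",
        stoichiometry={_c("adp"): -1, _c("pi"): -1, _c("h"): -1,
                       _c("atp"): 1, _c("h2o"): 1},
        reversibility="="))
    return db


# --- organisms -------------------------------------------------------------

PROFILES = ("complete", "fermenter", "single_gap", "auxotroph", "fragmented")

_SUBUNIT_GENES = {
    "GLCpts": [("ptsI", "subunit 1"), ("ptsH", "subunit 2")],
    "ATPS4r": [("atpA", "subunit 1"), ("atpB", "subunit 2")],
}

_TC_HEADER_TEMPLATES = [
    ("tglc", "4.A.1.1.1", "glucose PTS system"),
    ("tlac", "2.A.1.12.1", "d-lactate proton symporter"),
    ("tac", "1.A.14.1.1", "acetate channel"),
    ("tetoh", "1.A.8.1.1", "ethanol channel"),
    ("tpi", "2.A.20.1.1", "phosphate permease"),
    ("tala", "2.A.25.1.1", "l-alanine symporter"),
    ("thdca", "2.A.6.1.1", "palmitate permease"),
]


@dataclass
class ToyOrganism:
    id: str
    profile: str
    hits: list[HomologyHit]
    transporter_hits: list[HomologyHit]
    gram: str = "negative"
    gapfill_medium: str = "m9_glc"
    truth: dict = field(default_factory=dict)

    def write(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        save_hit_table(self.hits, d / f"{self.id}_hits.tsv")
        save_hit_table(self.transporter_hits, d / f"{self.id}_transporter_hits.tsv")


def _weak_map(profile: str) -> dict[str, float]:
    if profile == "fermenter":
        return dict(FERMENTER_WEAK)
    if profile == "single_gap":
        weak = dict(FERMENTER_WEAK)
        weak[SINGLE_GAP_REACTION] = -1.0  # no hit at all
        return weak
    if profile == "auxotroph":
        return dict(AUXOTROPH_WEAK)
    return {}


def make_toy_organism(world: ToyWorld, profile: str, seed: int = 1,
                      drop_probability: float = 0.0) -> ToyOrganism:
    """Generate an organism's hit tables and planted truth.

    Profiles: ``complete`` (strong evidence for every enzymatic
    reaction), ``fermenter`` (lactate dehydrogenase and the fructose
    route left below the direct cutoff), ``single_gap`` (fermenter with
    the anaplerotic carboxylase missing entirely), ``auxotroph``
    (alanine synthesis as core-only evidence, fatty-acid synthesis as
    non-core), ``fragmented`` (complete, with each hit independently
    dropped with ``drop_probability``).
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {PROFILES}")
    rng = np.random.default_rng(seed)
    org_id = f"org_{profile}_{seed}"
    weak = _weak_map(profile)
    hits: list[HomologyHit] = []
    for rid in sorted(world.db.reactions):
        rxn = world.db.reactions[rid]
        if rxn.is_spontaneous or rid in NO_REFERENCE_REACTIONS:
            continue
        if weak.get(rid, 0.0) < 0:
            continue  # planted gap: no evidence at all
        if rid in weak:
            bitscore = weak[rid]
            coverage = 80.0
        else:
            bitscore = float(np.round(rng.uniform(250.0, 420.0), 1))
            coverage = float(np.round(rng.uniform(80.0, 95.0), 1))
        identity = float(np.round(rng.uniform(60.0, 95.0), 1))
        if rid in COMPLEX_REACTIONS:
            for gene_suffix, label in _SUBUNIT_GENES[rid]:
                hits.append(HomologyHit(
                    f"{org_id}_{gene_suffix}", (rid,), bitscore, coverage,
                    identity, subunit_label=label))
        elif rid in ISOZYME_REACTIONS:
            for k in (1, 2):
                hits.append(HomologyHit(
                    f"{org_id}_{rid}_iso{k}", (rid,), bitscore, coverage,
                    identity))
        else:
            hits.append(HomologyHit(
                f"{org_id}_{rid}", (rid,), bitscore, coverage, identity))
    if profile == "fragmented":
        hits = [h for h in hits if rng.random() >= drop_probability]
    t_hits = []
    if profile != "fragmented" or drop_probability == 0.0:
        keep = _TC_HEADER_TEMPLATES
    else:
        keep = [t for t in _TC_HEADER_TEMPLATES
                if rng.random() >= drop_probability]
    for tag, tc, text in keep:
        t_hits.append(HomologyHit(
            f"{org_id}_{tag}|{tc}| {text}", (), 300.0, 85.0, 80.0))

    truth: dict = {"weak_reactions": sorted(weak)}
    if profile in ("complete", "fermenter", "single_gap"):
        absent = {"PWY_FERM_LAC", "PWY_FRUCTOSE"} if profile != "complete" else set()
        if profile == "single_gap":
            absent.add("PWY_ANAPLEROSIS")
        truth["present_pathways"] = sorted(
            {p.id for p in world.pathway_defs} - absent)
        truth["absent_pathways"] = sorted(absent)
    if profile == "single_gap":
        truth["step1_added"] = [SINGLE_GAP_REACTION]
    if profile == "fermenter":
        truth["step1_added"] = []
        truth["step3_added"] = {"fructose": ["FRK", "FRUabc"]}
        truth["step4_added"] = {"lactate": ["LDH_D"]}
        truth["essential_m9_glc"] = [
            f"{org_id}_PGI", f"{org_id}_MURS_toy",
            f"{org_id}_ptsI", f"{org_id}_ptsH"]
        truth["nonessential_m9_glc"] = [
            f"{org_id}_ACKr_iso1", f"{org_id}_ACKr_iso2",
            f"{org_id}_atpA", f"{org_id}_atpB"]
        truth["carbon_sources_positive"] = ["glucose", "fructose", "ethanol",
                                            "acetate"]
        truth["carbon_sources_negative"] = ["palmitate", "alanine", "lactate"]
    if profile == "auxotroph":
        truth["gapfill_medium"] = "complete"
        truth["step2_added"] = {_c("ala__L"): ["ALAD"]}
        truth["step2_unresolved_components"] = [_c("hdca")]
    org = ToyOrganism(org_id, profile, hits, t_hits, truth=truth)
    if profile == "auxotroph":
        org.gapfill_medium = "complete"
    return org
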