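"""Generators for miniature SNF-structured models and alignment fixtures.

:func:`generate_toy_snf_model` builds a ~60-reaction compartmentalised
bacteroid network whose qualitative behaviour mirrors the real system:
plant-supplied C4-dicarboxylate and glutamate, an eight-reaction TCA loop,
gluconeogenesis entered through a single-gene NAD-malic enzyme, a
two-reaction oxidative pentose phosphate proxy supplying NADPH, a
ferredoxin redox cycle, oxygen-capped respiration as the sole ATP source,
the nitrogenase reaction with its printed stoichiometry, amino-acid cycling
transaminations, and one gene-gated biosynthesis branch per nitrogenase
cofactor. The network topology is deterministic given the flags; the seed
only shuffles list order and decoy parameters, so ground-truth labels are
provable by construction.

Deliberate simplifications (see the package methods note): succinyl-CoA
synthetase is ATP-neutral (GTP not tracked) so respiration is provably the
sole ATP source; a small fixed-ammonia assimilation reaction feeds bacteroid
nitrogen metabolism from nitrogenase, which is what lets the model run on
glutamate alone and effuse glutamate when carbon is plentiful; the
glutamate transporter has a finite capacity (0.5 mmol/gDW/hr) so the
optimum stays carbon-limited and wasteful routes (glyoxylate shunt, PHB
cycle) are strictly suboptimal rather than merely unused.

:func:`generate_hit_tables` plants reciprocal-best-hit pairs among decoys
that each violate exactly one filter criterion, giving an exact expected
answer for the RBH filter. :func:`generate_tiny_model` emits random <= 8
reaction models for brute-force LP cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Set, Tuple

import numpy as np

from .model import Metabolite, Model, Reaction, ReactionKind, assert_valid
from .rbh import HitRecord
from .snf import (MediumSpec, ObjectiveSpec, apply_symbiotic_medium,
                  build_nitrogenase_reaction, build_nutrient_sharing_reaction,
                  default_snf_medium)

#: Cofactor branches in pool order: (pool species, branch description).
COFACTOR_ORDER = ("heme", "fes", "mobd", "hco", "pydx", "b12", "thm", "gsh")

#: Finite glutamate transporter capacity (mmol/gDW/hr): keeps the optimum
#: carbon-limited instead of purely oxygen-limited (see module docstring).
GLUTAMATE_TRANSPORT_CAPACITY = 0.5


@dataclass
class ToyModelConfig:
    seed: int = 0
    n_cofactor_branches: int = 8
    include_isozymes: bool = False
    include_glyoxylate_shunt: bool = True
    include_phb_branch: bool = True
    carbon_source: str = "malate"  # malate | succinate | glutamate_only

    def __post_init__(self) -> None:
        if not 1 <= self.n_cofactor_branches <= len(COFACTOR_ORDER):
            raise ValueError(
                f"n_cofactor_branches must be in [1, {len(COFACTOR_ORDER)}]")


@dataclass
class GroundTruth:
    essential_genes: FrozenSet[str] = frozenset()
    non_essential_genes: FrozenSet[str] = frozenset()
    expected_active_subsystems: FrozenSet[str] = frozenset()
    expected_inactive_subsystems: FrozenSet[str] = frozenset()
    rbh_pairs: FrozenSet[Tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        if self.essential_genes & self.non_essential_genes:
            raise ValueError("essential and non-essential sets overlap")


def _c(name: str) -> str:
    return f"{name}[c]"


def _e(name: str) -> str:
    return f"{name}[e]"


# (id, name) for every cytosolic metabolite of the full toy network
_CYTOSOL = [
    ("mal", "malate"), ("succ", "succinate"), ("fum", "fumarate"),
    ("oaa", "oxaloacetate"), ("cit", "citrate"), ("icit", "isocitrate"),
    ("akg", "2-oxoglutarate"), ("succoa", "succinyl-CoA"),
    ("coa", "coenzyme A"), ("pyr", "pyruvate"), ("accoa", "acetyl-CoA"),
    ("glx", "glyoxylate"), ("phb", "poly-hydroxybutyrate unit"),
    ("g6p", "glucose 6-phosphate"), ("p6g", "6-phosphogluconate"),
    ("ru5p", "ribulose 5-phosphate"),
    ("glu", "glutamate"), ("asp", "aspartate"), ("ala", "alanine"),
    ("arg", "arginine"), ("glycogen", "glycogen unit"),
    ("hdca", "hexadecanoate"),
    ("atp", "ATP"), ("adp", "ADP"), ("pi", "phosphate"),
    ("nad", "NAD+"), ("nadh", "NADH"), ("nadp", "NADP+"), ("nadph", "NADPH"),
    ("fdox", "ferredoxin (oxidized)"), ("fdred", "ferredoxin (reduced)"),
    ("o2", "oxygen"), ("n2", "dinitrogen"), ("nh3", "ammonia"),
    ("h", "proton"), ("co2", "carbon dioxide"), ("h2o", "water"),
    ("fe2", "iron(II)"), ("so4", "sulfate"), ("h2s", "hydrogen sulfide"),
    ("cyst", "cystathionine"), ("cys", "cysteine"),
    ("inost", "inositol"), ("mg2", "magnesium"), ("mobd", "molybdate"),
    ("hco", "homocitrate"),
    ("heme", "heme"), ("fes", "iron-sulfur cluster"),
    ("pydx", "pyridoxine phosphate"), ("b12", "adenosylcobalamin"),
    ("thm", "thiamine phosphate"), ("gsh", "glutathione"),
]

_EXTRACELLULAR = [
    ("mal", "malate"), ("succ", "succinate"), ("glu", "glutamate"),
    ("o2", "oxygen"), ("n2", "dinitrogen"), ("inost", "inositol"),
    ("fe2", "iron(II)"), ("so4", "sulfate"), ("pi", "phosphate"),
    ("hco", "homocitrate"), ("mg2", "magnesium"), ("mobd", "molybdate"),
    ("h", "proton"), ("co2", "carbon dioxide"), ("h2o", "water"),
    ("nh3", "ammonia"), ("ala", "alanine"), ("asp", "aspartate"),
]

# Cofactor branch definitions: species -> (gene, reaction id, stoichiometry,
# subsystem). Stoichiometries are written with helper lambdas below.
_BRANCH_SUBSYSTEM = {
    "heme": "Porphyrin and chlorophyll metabolism",
    "fes": "Iron-sulfur cluster biosynthesis",
    "mobd": "Transport",
    "hco": "Transport",
    "pydx": "Cofactor biosynthesis",
    "b12": "Cofactor biosynthesis",
    "thm": "Cofactor biosynthesis",
    "gsh": "Cofactor biosynthesis",
}

# Upstream gene dependencies per cofactor branch (used for ground truth).
_BRANCH_GENES = {
    "heme": {"hemA", "sitA"},
    "fes": {"iscU", "sitA", "cysH", "sulP", "metB", "cbs1"},
    "mobd": {"modA"},
    "hco": {"hcoT"},
    "pydx": {"pdxA", "pitA"},
    "b12": {"cobA", "mgtA"},
    "thm": {"thiC", "cysH", "sulP", "pitA"},
    "gsh": {"gshB", "cysH", "sulP", "metB", "cbs1"},
}

#: Genes essential regardless of which cofactor branches are included:
#: the carbon/energy/nitrogen core feeding the sharing reaction itself.
_CORE_ESSENTIAL = {
    "dme", "pdhA", "mdh", "pckA", "zwf", "gnd", "tktA",
    "ctaD", "ctaE", "fprA", "nifH", "nifD", "nifK",
    "argG", "aspC", "alaA", "glgA", "fabF",
}

#: Genes never essential in the default world: redundant carbon entries,
#: optional TCA segments and the deliberately wasteful branches.
_CORE_NON_ESSENTIAL = {
    "dctA", "aapJ", "gdhA", "gltA", "acnA", "icd", "sucA", "sucB",
    "sucCD", "sdhA", "fumC", "iolT",
}

#: Reactions duplicated behind isozyme OR-pairs when the flag is set.
_ISOZYME_PAIRS = {"ASPTA": ("aspC", "aspC2"),
                  "ALATA": ("alaA", "alaA2"),
                  "THMS": ("thiC", "thiC2")}


def _toy_reactions(config: ToyModelConfig) -> List[Reaction]:
    R = Reaction
    K = ReactionKind
    rxns: List[Reaction] = []

    def add(rid, stoich, lb, ub, gpr=None, subsystem=None, kind=K.INTERNAL,
            name=""):
        rxns.append(R(id=rid, name=name or rid, stoichiometry=stoich,
                      lower_bound=lb, upper_bound=ub, gpr=gpr,
                      subsystem=subsystem, kind=kind))

    branches = set(COFACTOR_ORDER[:config.n_cofactor_branches])

    # exchanges (kind exchange, bounds set later by the medium)
    skip_e = set()
    if "mobd" not in branches:
        skip_e.add("mobd")
    if "hco" not in branches:
        skip_e.add("hco")
    if not (branches & {"fes", "thm", "gsh"}):
        skip_e.add("so4")
    if not (branches & {"heme", "fes"}):
        skip_e.add("fe2")
    if "b12" not in branches:
        skip_e.add("mg2")
    for base, name in _EXTRACELLULAR:
        if base in skip_e:
            continue
        add(f"EX_{base}_e", {_e(base): -1.0}, 0.0, 1000.0,
            kind=K.EXCHANGE, name=f"{name} exchange")

    # transport
    add("DCTt", {_e("mal"): -1, _c("mal"): 1}, -1000, 1000, gpr="dctA",
        subsystem="Transport", name="C4-dicarboxylate transport (malate)")
    add("SUCCt", {_e("succ"): -1, _c("succ"): 1}, -1000, 1000, gpr="dctA",
        subsystem="Transport", name="C4-dicarboxylate transport (succinate)")
    cap = GLUTAMATE_TRANSPORT_CAPACITY
    add("GLUt", {_e("glu"): -1, _c("glu"): 1}, -cap, cap, gpr="aapJ",
        subsystem="Transport", name="glutamate transport (finite capacity)")
    add("O2t", {_e("o2"): -1, _c("o2"): 1}, -1000, 1000,
        subsystem="Transport", kind=K.SPONTANEOUS, name="oxygen diffusion")
    add("N2t", {_e("n2"): -1, _c("n2"): 1}, -1000, 1000,
        subsystem="Transport", kind=K.SPONTANEOUS, name="dinitrogen diffusion")
    add("CO2t", {_c("co2"): -1, _e("co2"): 1}, -1000, 1000,
        subsystem="Transport", kind=K.SPONTANEOUS, name="CO2 diffusion")
    add("H2Ot", {_e("h2o"): -1, _c("h2o"): 1}, -1000, 1000,
        subsystem="Transport", kind=K.SPONTANEOUS, name="water diffusion")
    add("Ht", {_c("h"): -1, _e("h"): 1}, -1000, 1000,
        subsystem="Transport", kind=K.SPONTANEOUS, name="proton diffusion")
    add("PIt", {_e("pi"): -1, _c("pi"): 1}, 0, 1000, gpr="pitA",
        subsystem="Transport", name="phosphate transport")
    if "fe2" not in skip_e:
        add("FE2t", {_e("fe2"): -1, _c("fe2"): 1}, 0, 1000, gpr="sitA",
            subsystem="Transport", name="iron(II) transport")
    if "so4" not in skip_e:
        add("SO4t", {_e("so4"): -1, _c("so4"): 1}, 0, 1000, gpr="sulP",
            subsystem="Transport", name="sulfate transport")
    if "hco" in branches:
        add("HCOt", {_e("hco"): -1, _c("hco"): 1}, 0, 1000, gpr="hcoT",
            subsystem="Transport", name="homocitrate import (plant-supplied)")
    if "mg2" not in skip_e:
        add("MG2t", {_e("mg2"): -1, _c("mg2"): 1}, 0, 1000, gpr="mgtA",
            subsystem="Transport", name="magnesium transport")
    if "mobd" in branches:
        add("MOBDt", {_e("mobd"): -1, _c("mobd"): 1}, 0, 1000, gpr="modA",
            subsystem="Transport", name="molybdate transport")
    add("INOSTt", {_e("inost"): -1, _c("inost"): 1}, 0, 1000, gpr="iolT",
        subsystem="Transport", name="inositol import")
    add("INOSD", {_c("inost"): -1}, 0, 1000,
        subsystem="Inositol metabolism", name="inositol sink (fate unknown)")

    # TCA cycle (8 reactions)
    tca = "Citrate cycle (TCA cycle)"
    add("MDH", {_c("mal"): -1, _c("nad"): -1, _c("oaa"): 1, _c("nadh"): 1},
        -1000, 1000, gpr="mdh", subsystem=tca, name="malate dehydrogenase")
    add("CS", {_c("accoa"): -1, _c("oaa"): -1, _c("h2o"): -1,
               _c("cit"): 1, _c("coa"): 1},
        0, 1000, gpr="gltA", subsystem=tca, name="citrate synthase")
    add("ACONT", {_c("cit"): -1, _c("icit"): 1}, -1000, 1000, gpr="acnA",
        subsystem=tca, name="aconitase")
    add("ICDH", {_c("icit"): -1, _c("nad"): -1,
                 _c("akg"): 1, _c("co2"): 1, _c("nadh"): 1},
        0, 1000, gpr="icd", subsystem=tca, name="isocitrate dehydrogenase")
    add("AKGDH", {_c("akg"): -1, _c("coa"): -1, _c("nad"): -1,
                  _c("succoa"): 1, _c("co2"): 1, _c("nadh"): 1},
        0, 1000, gpr="sucA and sucB", subsystem=tca,
        name="2-oxoglutarate dehydrogenase complex")
    # ATP-neutral proxy (GTP pool not tracked): keeps oxidative
    # phosphorylation the sole ATP source, so its genes have a provable label.
    add("SUCOAS", {_c("succoa"): -1, _c("h2o"): -1,
                   _c("succ"): 1, _c("coa"): 1},
        0, 1000, gpr="sucCD", subsystem=tca, name="succinyl-CoA synthetase")
    add("SUCD", {_c("succ"): -1, _c("nad"): -1, _c("fum"): 1, _c("nadh"): 1},
        0, 1000, gpr="sdhA", subsystem=tca, name="succinate dehydrogenase")
    add("FUM", {_c("fum"): -1, _c("h2o"): -1, _c("mal"): 1}, -1000, 1000,
        gpr="fumC", subsystem=tca, name="fumarase")

    # gluconeogenesis via NAD-malic enzyme (single-gene gate, Dme analogue)
    gng = "Gluconeogenesis"
    add("DME", {_c("mal"): -1, _c("nad"): -1,
                _c("pyr"): 1, _c("co2"): 1, _c("nadh"): 1},
        0, 1000, gpr="dme", subsystem=gng, name="NAD-malic enzyme")
    add("PDH", {_c("pyr"): -1, _c("coa"): -1, _c("nad"): -1,
                _c("accoa"): 1, _c("co2"): 1, _c("nadh"): 1},
        0, 1000, gpr="pdhA", subsystem="Pyruvate metabolism",
        name="pyruvate dehydrogenase")
    add("GNG", {_c("oaa"): -1, _c("atp"): -2, _c("nadh"): -1,
                _c("g6p"): 1, _c("adp"): 2, _c("pi"): 1, _c("nad"): 1},
        0, 1000, gpr="pckA", subsystem=gng,
        name="gluconeogenesis (lumped, oxaloacetate to G6P)")

    # pentose phosphate proxy (oxidative, 2 reactions) + pentose return
    ppp = "Pentose phosphate pathway"
    add("G6PDH", {_c("g6p"): -1, _c("nadp"): -1, _c("h2o"): -1,
                  _c("p6g"): 1, _c("nadph"): 1},
        0, 1000, gpr="zwf", subsystem=ppp,
        name="glucose-6-phosphate dehydrogenase (lumped with lactonase)")
    add("GND", {_c("p6g"): -1, _c("nadp"): -1,
                _c("ru5p"): 1, _c("co2"): 1, _c("nadph"): 1},
        0, 1000, gpr="gnd", subsystem=ppp,
        name="6-phosphogluconate dehydrogenase")
    add("TKT", {_c("ru5p"): -6, _c("g6p"): 5}, 0, 1000, gpr="tktA",
        subsystem=ppp, name="non-oxidative pentose return (lumped)")

    # respiration and ferredoxin redox
    oxp = "Oxidative phosphorylation"
    add("RESP", {_c("nadh"): -1, _c("o2"): -0.5, _c("adp"): -2, _c("pi"): -2,
                 _c("nad"): 1, _c("atp"): 2, _c("h2o"): 2},
        0, 1000, gpr="ctaD and ctaE", subsystem=oxp,
        name="respiratory chain (P/O = 2)")
    add("FNR", {_c("nadh"): -1, _c("fdox"): -2, _c("nad"): 1, _c("fdred"): 2},
        0, 1000, gpr="fprA", subsystem=oxp,
        name="NADH:ferredoxin oxidoreductase")

    # nitrogen and amino-acid cycling
    aam = "Amino acid metabolism"
    add("GDH", {_c("glu"): -1, _c("nad"): -1, _c("h2o"): -1,
                _c("akg"): 1, _c("nh3"): 1, _c("nadh"): 1},
        -1000, 1000, gpr="gdhA", subsystem=aam,
        name="glutamate dehydrogenase")
    add("ASPTA", {_c("glu"): -1, _c("oaa"): -1, _c("akg"): 1, _c("asp"): 1},
        0, 1000, gpr="aspC", subsystem=aam,
        name="aspartate transaminase")
    add("ALATA", {_c("glu"): -1, _c("pyr"): -1, _c("akg"): 1, _c("ala"): 1},
        0, 1000, gpr="alaA", subsystem=aam, name="alanine transaminase")
    add("ARGS", {_c("glu"): -1, _c("nh3"): -1, _c("atp"): -2,
                 _c("arg"): 1, _c("adp"): 2, _c("pi"): 2},
        0, 1000, gpr="argG", subsystem=aam,
        name="arginine biosynthesis (lumped)")
    # small assimilation of nitrogenase-fixed ammonia into bacteroid
    # metabolism (GS proxy); exported ammonia still comes only from the pool.
    add("NH3AS", {_c("nh3fix"): -1, _c("nh3"): 1}, 0, 1000,
        subsystem=aam, name="fixed-ammonia assimilation (GS proxy)")
    # surplus ammonium from amino-acid deamination leaves by diffusion;
    # without this valve glutamate could not serve as sole carbon source
    # (every deamination event would strand one nitrogen).
    add("AMT", {_c("nh3"): -1, _e("nh3"): 1}, 0, 1000,
        subsystem="Transport", kind=K.SPONTANEOUS,
        name="ammonium efflux (diffusion)")

    # storage compounds consumed by the sharing reaction
    add("GLYS", {_c("g6p"): -1, _c("atp"): -1,
                 _c("glycogen"): 1, _c("adp"): 1, _c("pi"): 2},
        0, 1000, gpr="glgA", subsystem="Glycogen metabolism",
        name="glycogen synthase (per glucose unit)")
    add("FAS", {_c("accoa"): -8, _c("nadph"): -14, _c("atp"): -7,
                _c("hdca"): 1, _c("coa"): 8, _c("nadp"): 14,
                _c("adp"): 7, _c("pi"): 7},
        0, 1000, gpr="fabF", subsystem="Fatty acid biosynthesis",
        name="fatty acid synthesis (C16, lumped)")

    # sulfur assimilation and the cysteine branch (CBS gap exemplar)
    sul = "Sulfur metabolism"
    if "so4" not in skip_e:
        add("SADT", {_c("so4"): -1, _c("atp"): -1, _c("nadph"): -4,
                     _c("h2s"): 1, _c("adp"): 1, _c("pi"): 1, _c("nadp"): 4},
            0, 1000, gpr="cysH", subsystem=sul,
            name="assimilatory sulfate reduction (lumped)")
    if branches & {"fes", "gsh"}:
        add("CTHS", {_c("glu"): -1, _c("h2s"): -1, _c("atp"): -1,
                     _c("cyst"): 1, _c("adp"): 1, _c("pi"): 1},
            0, 1000, gpr="metB", subsystem=sul,
            name="cystathionine synthesis (lumped)")
        add("CBS", {_c("cyst"): -1, _c("h2o"): -1, _c("cys"): 1, _c("nh3"): 1},
            0, 1000, gpr="cbs1", subsystem=sul,
            name="cystathionine beta-synthase analogue")

    # cofactor branches (one gene gate each)
    cof = "Cofactor biosynthesis"
    if "heme" in branches:
        add("HEMES", {_c("glu"): -1, _c("fe2"): -1, _c("nadph"): -1,
                      _c("heme"): 1, _c("nadp"): 1},
            0, 1000, gpr="hemA",
            subsystem="Porphyrin and chlorophyll metabolism",
            name="heme biosynthesis (lumped from glutamate)")
    if "fes" in branches:
        add("FESS", {_c("cys"): -1, _c("fe2"): -1, _c("atp"): -1,
                     _c("fes"): 1, _c("adp"): 1, _c("pi"): 1},
            0, 1000, gpr="iscU",
            subsystem="Iron-sulfur cluster biosynthesis",
            name="FeS cluster assembly")
    if "pydx" in branches:
        add("PYDXS", {_c("ru5p"): -1, _c("glu"): -1, _c("atp"): -1,
                      _c("pydx"): 1, _c("adp"): 1},
            0, 1000, gpr="pdxA", subsystem=cof, name="pyridoxine biosynthesis")
    if "b12" in branches:
        add("B12S", {_c("glu"): -1, _c("mg2"): -1, _c("atp"): -8,
                     _c("b12"): 1, _c("adp"): 8, _c("pi"): 8},
            0, 1000, gpr="cobA", subsystem=cof,
            name="cobalamin biosynthesis (lumped; divalent metal proxy)")
    if "thm" in branches:
        add("THMS", {_c("ru5p"): -1, _c("h2s"): -1, _c("atp"): -1,
                     _c("thm"): 1, _c("adp"): 1},
            0, 1000, gpr="thiC", subsystem=cof, name="thiamine biosynthesis")
    if "gsh" in branches:
        add("GSHS", {_c("glu"): -1, _c("cys"): -1, _c("atp"): -1,
                     _c("gsh"): 1, _c("adp"): 1, _c("pi"): 1},
            0, 1000, gpr="gshB", subsystem=cof,
            name="glutathione biosynthesis (lumped)")

    # optional, deliberately wasteful branches
    if config.include_glyoxylate_shunt:
        gs = "Glyoxylate shunt"
        add("ICL", {_c("icit"): -1, _c("succ"): 1, _c("glx"): 1},
            0, 1000, gpr="aceA", subsystem=gs, name="isocitrate lyase")
        add("MALS", {_c("glx"): -1, _c("accoa"): -1, _c("h2o"): -1,
                     _c("mal"): 1, _c("coa"): 1},
            0, 1000, gpr="aceB", subsystem=gs, name="malate synthase")
    if config.include_phb_branch:
        phb = "Poly-hydroxybutyrate cycle"
        add("PHBS", {_c("accoa"): -2, _c("nadph"): -1,
                     _c("phb"): 1, _c("coa"): 2, _c("nadp"): 1},
            0, 1000, gpr="phbB", subsystem=phb, name="PHB synthesis (lumped)")
        add("PHBD", {_c("phb"): -1, _c("coa"): -2, _c("nad"): -1,
                     _c("atp"): -1, _c("accoa"): 2, _c("nadh"): 1,
                     _c("adp"): 1, _c("pi"): 1},
            0, 1000, gpr="bdhA", subsystem=phb,
            name="PHB degradation (lumped)")

    if config.include_isozymes:
        for rid, (g1, g2) in _ISOZYME_PAIRS.items():
            for rxn in rxns:
                if rxn.id == rid:
                    rxn.gpr = f"{g1} or {g2}"
                    rxn.__post_init__()
    return rxns


def _toy_metabolites(config: ToyModelConfig,
                     reactions: List[Reaction]) -> List[Metabolite]:
    used: Set[str] = set()
    for rxn in reactions:
        used |= set(rxn.stoichiometry)
    mets: List[Metabolite] = []
    for base, name in _CYTOSOL:
        mid = _c(base)
        if mid in used:
            mets.append(Metabolite(id=mid, name=name, compartment="c"))
    for base, name in _EXTRACELLULAR:
        mid = _e(base)
        if mid in used:
            mets.append(Metabolite(id=mid, name=name, compartment="e"))
    return mets


def toy_ground_truth(config: ToyModelConfig) -> GroundTruth:
    """Ground-truth labels implied by the toy network's construction.

    A gene is essential iff it gates (alone, or as an AND-complex member)
    the only route to something the nutrient-sharing reaction consumes;
    OR-pair isozymes and bypassable segments are non-essential.
    """
    branches = set(COFACTOR_ORDER[:config.n_cofactor_branches])
    essential = set(_CORE_ESSENTIAL)
    non_essential = set(_CORE_NON_ESSENTIAL)
    branch_genes: Set[str] = set()
    for b in branches:
        branch_genes |= _BRANCH_GENES[b]
    # sulfate/iron/etc transporters matter only while some included branch
    # consumes them, which _BRANCH_GENES already encodes.
    essential |= branch_genes
    # phosphate import is needed only for the net P drain into
    # phosphorylated cofactors (pydx, thm).
    if not branches & {"pydx", "thm"}:
        essential.discard("pitA")
        non_essential.add("pitA")
    if config.include_glyoxylate_shunt:
        non_essential |= {"aceA", "aceB"}
    if config.include_phb_branch:
        non_essential |= {"phbB", "bdhA"}
    if config.include_isozymes:
        for g1, g2 in _ISOZYME_PAIRS.values():
            essential.discard(g1)
            non_essential |= {g1, g2}

    active = {"Citrate cycle (TCA cycle)", "Pentose phosphate pathway",
              "Oxidative phosphorylation", "Nitrogen fixation",
              "Gluconeogenesis", "Amino acid metabolism"}
    if branches & {"fes", "thm", "gsh"}:
        active.add("Sulfur metabolism")
    if "heme" in branches:
        active.add("Porphyrin and chlorophyll metabolism")
    inactive = set()
    if config.include_glyoxylate_shunt:
        inactive.add("Glyoxylate shunt")
    if config.include_phb_branch:
        inactive.add("Poly-hydroxybutyrate cycle")
    return GroundTruth(
        essential_genes=frozenset(essential),
        non_essential_genes=frozenset(non_essential),
        expected_active_subsystems=frozenset(active),
        expected_inactive_subsystems=frozenset(inactive))


def generate_toy_snf_model(config: Optional[ToyModelConfig] = None,
                           apply_medium: bool = True
                           ) -> Tuple[Model, GroundTruth]:
    """Build the toy bacteroid model plus its ground-truth labels.

    The returned model already carries the nitrogenase and nutrient-sharing
    objective reactions and, unless ``apply_medium`` is false, the default
    symbiotic medium for ``config.carbon_source``. The seed shuffles the
    metabolite/reaction list order only; topology is deterministic.
    """
    config = config or ToyModelConfig()
    rng = np.random.default_rng(config.seed)

    reactions = _toy_reactions(config)
    model = Model(id=f"toy_snf_{config.seed}",
                  name="synthetic SNF bacteroid network")
    for met in _toy_metabolites(config, reactions):
        model.add_metabolite(met)
    for rxn in reactions:
        model.add_reaction(rxn)

    model = build_nitrogenase_reaction(model, gpr="nifH and nifD and nifK")
    branches = COFACTOR_ORDER[:config.n_cofactor_branches]
    spec = ObjectiveSpec(
        cofactor_components=tuple(_c(b) for b in branches))
    model = build_nutrient_sharing_reaction(model, spec)

    if apply_medium:
        medium = default_snf_medium(carbon_source=config.carbon_source)
        medium.bounds = {k: v for k, v in medium.bounds.items()
                         if model.has_reaction(k)}
        apply_symbiotic_medium(model, medium)

    # seed-controlled presentation order; never changes the network itself
    met_order = rng.permutation(len(model.metabolites))
    rxn_order = rng.permutation(len(model.reactions))
    model.metabolites = [model.metabolites[i] for i in met_order]
    model.reactions = [model.reactions[i] for i in rxn_order]
    model.genes = sorted(model.genes)

    assert_valid(model)
    return model, toy_ground_truth(config)


def surplus_carbon_medium(malate_factor: float = 20.0,
                          oxygen_factor: float = 100.0) -> MediumSpec:
    """Default medium with carbon and oxygen made non-limiting.

    Used to probe the carbon/nitrogen balance of the toy model: with malate
    and oxygen in excess the optimum is capped by the trace homocitrate
    supply, ATP is in surplus, and the model can synthesise and effuse
    glutamate instead of importing it.
    """
    medium = default_snf_medium()
    lb, ub = medium.bounds["EX_mal_e"]
    medium.bounds["EX_mal_e"] = (lb * malate_factor, ub)
    lb, ub = medium.bounds["EX_o2_e"]
    medium.bounds["EX_o2_e"] = (lb * oxygen_factor, ub)
    return medium


# -- random tiny models for LP oracle cross-checks ------------------------

def generate_tiny_model(seed: int, max_reactions: int = 8) -> Model:
    """A random linear pathway model with <= ``max_reactions`` reactions.

    Structure: one uptake exchange, a chain of conversions with random
    coefficients and finite random bounds, optionally a parallel duplicate
    branch, and a terminal sink which is the objective. All bounds are
    finite so the flux polytope has vertices and a brute-force vertex
    enumeration oracle applies.
    """
    rng = np.random.default_rng(seed)
    n_chain = int(rng.integers(2, max(3, max_reactions - 2)))
    parallel = bool(rng.integers(0, 2)) and n_chain + 3 <= max_reactions
    mets = [f"m{i}[c]" for i in range(n_chain)]

    model = Model(id=f"tiny_{seed}")
    model.add_metabolite(Metabolite(id="s[e]", compartment="e"))
    for mid in mets:
        model.add_metabolite(Metabolite(id=mid, compartment="c"))

    uptake = float(np.round(rng.uniform(1.0, 10.0), 3))
    model.add_reaction(Reaction(
        id="EX_s_e", stoichiometry={"s[e]": -1.0},
        lower_bound=-uptake, upper_bound=0.0, kind=ReactionKind.EXCHANGE))
    model.add_reaction(Reaction(
        id="T0", stoichiometry={"s[e]": -1.0, mets[0]: 1.0},
        lower_bound=0.0, upper_bound=float(np.round(rng.uniform(5, 20), 3))))
    for i in range(n_chain - 1):
        coef = float(rng.integers(1, 3))
        model.add_reaction(Reaction(
            id=f"C{i}",
            stoichiometry={mets[i]: -1.0, mets[i + 1]: coef},
            lower_bound=0.0,
            upper_bound=float(np.round(rng.uniform(2, 20), 3))))
    if parallel:
        model.add_reaction(Reaction(
            id="C0b",
            stoichiometry={mets[0]: -1.0, mets[1]: 1.0},
            lower_bound=0.0,
            upper_bound=float(np.round(rng.uniform(2, 20), 3))))
    model.add_reaction(Reaction(
        id="OF_sink", stoichiometry={mets[-1]: -1.0},
        lower_bound=0.0, upper_bound=float(np.round(rng.uniform(5, 50), 3)),
        kind=ReactionKind.OBJECTIVE_PSEUDO))
    model.objective_reaction_ids = ["OF_sink"]
    assert_valid(model)
    return model


# -- alignment-hit fixtures ----------------------------------------------

def generate_hit_tables(n_true_pairs: int, n_decoys: int, seed: int
                        ) -> Tuple[List[HitRecord], List[HitRecord],
                                   FrozenSet[Tuple[str, str]]]:
    """Forward/reverse hit tables with planted reciprocal best hits.

    Planted pairs pass every criterion in both directions. Each decoy
    violates exactly one rule: E-value too high, identity at or below the
    strict 30% threshold, coverage at or below the strict 60% threshold, or
    broken reciprocity (the subject's best hit is a different query). The
    RBH filter must return exactly the planted set.
    """
    if n_true_pairs < 0 or n_decoys < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    forward: List[HitRecord] = []
    reverse: List[HitRecord] = []
    planted: Set[Tuple[str, str]] = set()

    def good(q, s):
        qlen = int(rng.integers(200, 900))
        alen = int(qlen * rng.uniform(0.70, 0.98))
        return HitRecord(
            query=q, subject=s,
            e_value=float(10.0 ** rng.uniform(-120, -10)),
            percent_identity=float(np.round(rng.uniform(35, 95), 1)),
            alignment_length=alen, query_length=qlen,
            bitscore=float(np.round(rng.uniform(80, 900), 1)))

    for i in range(n_true_pairs):
        q, s = f"qa{i:03d}", f"sb{i:03d}"
        forward.append(good(q, s))
        reverse.append(good(s, q))
        planted.add((q, s))

    mode_cycle = ["evalue", "identity", "coverage", "reciprocity"]
    for i in range(n_decoys):
        mode = mode_cycle[i % len(mode_cycle)]
        q, s = f"dq{i:03d}", f"ds{i:03d}"
        fwd = good(q, s)
        rev = good(s, q)
        if mode == "evalue":
            fwd.e_value = float(10.0 ** rng.uniform(-5.9, -1))  # >= 1e-6
        elif mode == "identity":
            # exactly at or below the strict threshold
            fwd.percent_identity = float(
                rng.choice([30.0, np.round(rng.uniform(5, 29.9), 1)]))
        elif mode == "coverage":
            if rng.integers(0, 2):
                # exactly on the strict 60% boundary
                fwd.query_length = 500
                fwd.alignment_length = 300
            else:
                frac = float(rng.uniform(0.1, 0.55))
                fwd.alignment_length = max(
                    1, int(fwd.query_length * frac))
        else:  # reciprocity: s's best hit is some other query
            better = good(s, f"zz{i:03d}")
            better.e_value = rev.e_value / 10.0
            better.bitscore = rev.bitscore + 50.0
            reverse.append(better)
        forward.append(fwd)
        reverse.append(rev)

    rng.shuffle(forward)
    rng.shuffle(reverse)
    return forward, reverse, frozenset(planted)
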