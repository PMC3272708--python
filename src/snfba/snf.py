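"""The symbiotic-nitrogen-fixation (SNF) environment.

Bacteroids do not grow; their objective is not biomass but the coupled pair
of (1) a *nutrient-sharing* pseudo-reaction exporting alanine, aspartate and
ammonia to the plant while accumulating arginine, glycogen, hexadecanoate
and a nitrogenase cofactor pool, and (2) the *nitrogenase* reaction::

    16 ATP + 6 Fd_red + 16 H2O + N2 ->
        16 ADP + 6 Fd_ox + 8 H+ + 2 NH3 + 16 Pi

Coupling is structural: nitrogenase produces a dedicated fixed-ammonia pool
species (``nh3fix[c]``) and the nutrient-sharing reaction consumes it, so in
every feasible solution the ammonia exported to the plant is at most twice
the nitrogenase flux — fixed-N provenance is a constraint, not a post-hoc
check. A weighted-sum objective mode over both reactions is provided for
comparison.

The symbiotic medium encodes the microaerobic bacteroid habitat: a plant-
supplied C4-dicarboxylate (malate 1.112 or succinate 1.326 mmol/gDW/hr),
oxygen capped at 1.26, inositol at 0.01, freely exchanged glutamate, and
open mineral exchanges. Uptake is negative flux through an exchange reaction
written ``M[e] ->``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import yaml

from .model import Metabolite, Model, Reaction, ReactionKind

# -- canonical species ids (override per model via the ``species`` maps) ---

DEFAULT_SPECIES: Dict[str, str] = {
    "atp": "atp[c]", "adp": "adp[c]", "pi": "pi[c]", "h2o": "h2o[c]",
    "fdred": "fdred[c]", "fdox": "fdox[c]", "n2": "n2[c]", "h": "h[c]",
    "nh3": "nh3[c]", "nh3fix": "nh3fix[c]",
    "ala": "ala[c]", "asp": "asp[c]", "arg": "arg[c]",
    "glycogen": "glycogen[c]", "hdca": "hdca[c]", "cofact": "cofact[c]",
    "ala_e": "ala[e]", "asp_e": "asp[e]", "nh3_e": "nh3[e]",
}

#: The eight cofactor-pool members: nitrogenase prosthetic groups (heme,
#: FeS cluster, molybdenum cofactor, homocitrate) plus housekeeping
#: cofactors seen in bacteroid proteomes (pyridoxine, adenosylcobalamin,
#: thiamine, glutathione). Combined equimolar by default.
DEFAULT_COFACTOR_COMPONENTS: Tuple[str, ...] = (
    "heme[c]", "fes[c]", "mobd[c]", "hco[c]",
    "pydx[c]", "b12[c]", "thm[c]", "gsh[c]",
)

NITROGENASE_ID = "NASE"
NUTRIENT_SHARING_ID = "OF_nutrient_sharing"
COFACTOR_POOL_ID = "OF_cofactor_pool"

#: Printed nitrogenase stoichiometry: substrates (negative) and products.
NITROGENASE_STOICHIOMETRY: Dict[str, float] = {
    "atp": -16, "fdred": -6, "h2o": -16, "n2": -1,
    "adp": 16, "fdox": 6, "h": 8, "nh3fix": 2, "pi": 16,
}


@dataclass
class ObjectiveSpec:
    """Configuration of the coupled SNF objective."""

    cofactor_components: Tuple[str, ...] = DEFAULT_COFACTOR_COMPONENTS
    cofactor_coefficient: float = 0.01
    coupling_mode: str = "pool"  # "pool" | "weighted_sum"
    weights: Tuple[float, float] = (1.0, 1.0)  # (sharing, nitrogenase)
    species: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cofactor_coefficient <= 0:
            raise ValueError("cofactor_coefficient must be > 0")
        if self.coupling_mode not in ("pool", "weighted_sum"):
            raise ValueError(f"unknown coupling_mode {self.coupling_mode!r}")

    def species_map(self) -> Dict[str, str]:
        out = dict(DEFAULT_SPECIES)
        out.update(self.species)
        return out


@dataclass
class MediumSpec:
    """Named exchange-bound settings (mmol/gDW/hr) for the symbiotic habitat.

    ``bounds`` maps exchange-reaction id to (lower, upper). The carbon
    source selects which C4-dicarboxylate exchange stays open; under
    ``glutamate_only`` both are closed and glutamate is the sole carbon and
    nitrogen source.
    """

    bounds: Dict[str, Tuple[float, float]]
    carbon_source: str = "malate"  # malate | succinate | glutamate_only
    malate_exchange: str = "EX_mal_e"
    succinate_exchange: str = "EX_succ_e"

    def __post_init__(self) -> None:
        if self.carbon_source not in ("malate", "succinate", "glutamate_only"):
            raise ValueError(f"unknown carbon_source {self.carbon_source!r}")

    def effective_bounds(self) -> Dict[str, Tuple[float, float]]:
        """Bounds with the non-selected carbon exchange(s) closed to uptake."""
        out = {k: tuple(v) for k, v in self.bounds.items()}
        closed = {"malate": [self.succinate_exchange],
                  "succinate": [self.malate_exchange],
                  "glutamate_only": [self.malate_exchange,
                                     self.succinate_exchange]}
        for ex in closed[self.carbon_source]:
            if ex in out:
                out[ex] = (0.0, out[ex][1])
        return out


def _require_species(model: Model, ids: List[str], context: str) -> None:
    missing = sorted(i for i in ids if not model.has_metabolite(i))
    if missing:
        raise ValueError(f"{context}: model {model.id!r} is missing required "
                         f"species {missing}")


def build_nitrogenase_reaction(model: Model,
                               species: Optional[Dict[str, str]] = None,
                               gpr: Optional[str] = None,
                               reaction_id: str = NITROGENASE_ID) -> Model:
    """Add the nitrogenase reaction with the printed stoichiometry.

    Fixed ammonia goes into the dedicated pool species (created if absent);
    the reaction is irreversible. Modifies and returns ``model``.
    """
    smap = dict(DEFAULT_SPECIES)
    if species:
        smap.update(species)
    required = [smap[k] for k in
                ("atp", "adp", "pi", "h2o", "fdred", "fdox", "n2", "h", "nh3")]
    _require_species(model, required, "build_nitrogenase_reaction")
    if not model.has_metabolite(smap["nh3fix"]):
        model.add_metabolite(Metabolite(
            id=smap["nh3fix"], name="ammonia (nitrogenase-fixed pool)",
            compartment="c"))
    stoich = {smap[k]: float(c) for k, c in NITROGENASE_STOICHIOMETRY.items()}
    model.add_reaction(Reaction(
        id=reaction_id, name="nitrogenase",
        stoichiometry=stoich, lower_bound=0.0, upper_bound=1000.0,
        gpr=gpr, subsystem="Nitrogen fixation", kind=ReactionKind.INTERNAL))
    return model


def build_nutrient_sharing_reaction(model: Model,
                                    spec: Optional[ObjectiveSpec] = None
                                    ) -> Model:
    """Add the cofactor-pool and nutrient-sharing reactions; set objective.

    The cofactor-assembly pseudo-reaction combines the spec's components
    (equimolar by default) into one pool species consumed at
    ``cofactor_coefficient`` per unit of sharing flux. The sharing reaction
    consumes cytosolic Ala/Asp/Arg/glycogen/hexadecanoate and pool ammonia,
    and exports Ala/Asp/NH3 to the plant; it becomes the model objective
    (plus nitrogenase, weighted 1:1, in ``weighted_sum`` mode).
    """
    spec = spec or ObjectiveSpec()
    smap = spec.species_map()
    required = [smap[k] for k in ("ala", "asp", "arg", "glycogen", "hdca",
                                  "nh3fix", "ala_e", "asp_e", "nh3_e")]
    required += list(spec.cofactor_components)
    _require_species(model, required, "build_nutrient_sharing_reaction")

    if not model.has_metabolite(smap["cofact"]):
        model.add_metabolite(Metabolite(
            id=smap["cofact"], name="nitrogenase cofactor pool",
            compartment="c"))
    pool_stoich = {comp: -1.0 for comp in spec.cofactor_components}
    pool_stoich[smap["cofact"]] = 1.0
    model.add_reaction(Reaction(
        id=COFACTOR_POOL_ID, name="nitrogenase cofactor assembly",
        stoichiometry=pool_stoich, lower_bound=0.0, upper_bound=1000.0,
        kind=ReactionKind.OBJECTIVE_PSEUDO))

    sharing = {
        smap["ala"]: -1.0, smap["asp"]: -1.0, smap["arg"]: -1.0,
        smap["glycogen"]: -1.0, smap["hdca"]: -1.0, smap["nh3fix"]: -1.0,
        smap["cofact"]: -spec.cofactor_coefficient,
        smap["ala_e"]: 1.0, smap["asp_e"]: 1.0, smap["nh3_e"]: 1.0,
    }
    model.add_reaction(Reaction(
        id=NUTRIENT_SHARING_ID, name="nutrient sharing with host plant",
        stoichiometry=sharing, lower_bound=0.0, upper_bound=1000.0,
        kind=ReactionKind.OBJECTIVE_PSEUDO))

    if spec.coupling_mode == "pool":
        model.objective_reaction_ids = [NUTRIENT_SHARING_ID]
    else:
        model.objective_reaction_ids = [NUTRIENT_SHARING_ID, NITROGENASE_ID]
    return model


def objective_weights(model: Model, spec: ObjectiveSpec
                      ) -> Optional[Dict[str, float]]:
    """Explicit weights for :func:`snfba.fba.solve_fba` per coupling mode."""
    if spec.coupling_mode == "pool":
        return None
    w_share, w_nase = spec.weights
    return {NUTRIENT_SHARING_ID: w_share, NITROGENASE_ID: w_nase}


def apply_symbiotic_medium(model: Model, medium: MediumSpec) -> Model:
    """Set exchange bounds per the medium spec; error on unknown exchanges."""
    for ex_id, (lb, ub) in sorted(medium.effective_bounds().items()):
        if not model.has_reaction(ex_id):
            raise KeyError(
                f"medium names exchange {ex_id!r} absent from model "
                f"{model.id!r}")
        rxn = model.reaction(ex_id)
        if rxn.kind is not ReactionKind.EXCHANGE:
            raise ValueError(f"{ex_id!r} is not an exchange reaction")
        rxn.lower_bound, rxn.upper_bound = float(lb), float(ub)
    return model


# -- medium (de)serialisation ---------------------------------------------

def load_medium(path: str) -> MediumSpec:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return MediumSpec(
        bounds={k: (float(v[0]), float(v[1]))
                for k, v in raw["exchanges"].items()},
        carbon_source=raw.get("carbon_source", "malate"),
        malate_exchange=raw.get("malate_exchange", "EX_mal_e"),
        succinate_exchange=raw.get("succinate_exchange", "EX_succ_e"))


def save_medium(medium: MediumSpec, path: str) -> None:
    raw = {
        "carbon_source": medium.carbon_source,
        "malate_exchange": medium.malate_exchange,
        "succinate_exchange": medium.succinate_exchange,
        "exchanges": {k: [float(v[0]), float(v[1])]
                      for k, v in sorted(medium.bounds.items())},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def default_snf_medium(carbon_source: str = "malate") -> MediumSpec:
    """The shipped symbiotic medium (packaged ``data/snf_medium.yaml``)."""
    ref = importlib.resources.files("snfba") / "data" / "snf_medium.yaml"
    with importlib.resources.as_file(ref) as path:
        medium = load_medium(str(path))
    medium.carbon_source = carbon_source
    return medium
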