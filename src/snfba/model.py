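"""Core domain types for compartmentalised metabolic models.

A :class:`Model` is a plain in-memory container for a genome-scale (or toy)
metabolic network: metabolites with a cytosol/extracellular compartment,
reactions with stoichiometry, flux bounds in mmol/gDW/hr and an optional
Boolean gene-protein-reaction (GPR) association, and the list of genes.

Conventions
-----------
* Metabolite ids carry a compartment suffix, e.g. ``mal[c]`` / ``mal[e]``.
* An exchange reaction is written ``M[e] ->`` (stoichiometry ``{M[e]: -1}``):
  negative flux means uptake into the system, positive flux means excretion.
* A reaction is *reversible* exactly when its lower bound is negative.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Optional

from .gpr import GprTree, gpr_genes, parse_gpr

COMPARTMENTS = ("c", "e")

#: Default bounds (mmol/gDW/hr) used when an input format omits them.
DEFAULT_BOUND = 1000.0


class ReactionKind(str, Enum):
    """How a reaction participates in the network."""

    INTERNAL = "internal"
    EXCHANGE = "exchange"
    SPONTANEOUS = "spontaneous"
    OBJECTIVE_PSEUDO = "objective_pseudo"


#: Reaction-id prefixes recognised as objective pseudo-reactions on import.
OBJECTIVE_ID_PREFIXES = ("OF_",)


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.name:
            self.name = self.id


@dataclass
class Reaction:
    """A stoichiometric reaction.

    ``stoichiometry`` maps metabolite id to a signed coefficient
    (negative = consumed, positive = produced).
    """

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    name: str = ""
    gpr: Optional[GprTree] = None
    subsystem: Optional[str] = None
    kind: ReactionKind = ReactionKind.INTERNAL

    def __post_init__(self) -> None:
        if not self.name:
            self.name = self.id
        if isinstance(self.gpr, str):
            self.gpr = parse_gpr(self.gpr) if self.gpr.strip() else None
        if isinstance(self.kind, str):
            self.kind = ReactionKind(self.kind)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def genes(self) -> frozenset:
        return gpr_genes(self.gpr) if self.gpr is not None else frozenset()

    def equation(self) -> str:
        """Human-readable equation string, ``2 a[c] + b[c] -> c[c]``."""
        def side(items):
            parts = []
            for met, coef in items:
                coef = abs(coef)
                if coef == 1:
                    parts.append(met)
                else:
                    parts.append(f"{coef:g} {met}")
            return " + ".join(parts)

        subs = sorted((m, c) for m, c in self.stoichiometry.items() if c < 0)
        prods = sorted((m, c) for m, c in self.stoichiometry.items() if c > 0)
        arrow = "<=>" if self.reversible else "->"
        return f"{side(subs)} {arrow} {side(prods)}".strip()


@dataclass
class Model:
    id: str
    metabolites: List[Metabolite] = field(default_factory=list)
    reactions: List[Reaction] = field(default_factory=list)
    genes: List[str] = field(default_factory=list)
    objective_reaction_ids: List[str] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            self.name = self.id

    # -- lookups ---------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self._met_index()[met_id]
        except KeyError:
            raise KeyError(f"no metabolite {met_id!r} in model {self.id!r}")

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self._rxn_index()[rxn_id]
        except KeyError:
            raise KeyError(f"no reaction {rxn_id!r} in model {self.id!r}")

    def _met_index(self) -> Dict[str, Metabolite]:
        return {m.id: m for m in self.metabolites}

    def _rxn_index(self) -> Dict[str, Reaction]:
        return {r.id: r for r in self.reactions}

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index()

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index()

    def exchanges(self) -> List[Reaction]:
        return [r for r in self.reactions if r.kind is ReactionKind.EXCHANGE]

    def copy(self) -> "Model":
        return copy.deepcopy(self)

    def add_metabolite(self, met: Metabolite) -> None:
        if self.has_metabolite(met.id):
            raise ValueError(f"duplicate metabolite id {met.id!r}")
        self.metabolites.append(met)

    def add_reaction(self, rxn: Reaction) -> None:
        if self.has_reaction(rxn.id):
            raise ValueError(f"duplicate reaction id {rxn.id!r}")
        self.reactions.append(rxn)
        for g in sorted(rxn.genes):
            if g not in self.genes:
                self.genes.append(g)


@dataclass
class ModelSummary:
    """Headline counts in the style of published reconstruction tables.

    ``n_reactions_total`` counts internal reactions (gene-associated +
    non-gene-associated + spontaneous); exchange and objective
    pseudo-reactions are reported separately.
    """

    n_genes: int
    n_metabolites: int
    n_reactions_total: int
    n_gene_associated: int
    n_non_gene_associated: int
    n_spontaneous: int
    n_exchange: int

    def as_dict(self) -> Dict[str, int]:
        return dict(self.__dict__)

    def pretty(self) -> str:
        rows = [
            ("Included genes", self.n_genes),
            ("Total reactions", self.n_reactions_total),
            ("Gene-associated reactions", self.n_gene_associated),
            ("Non-gene-associated reactions", self.n_non_gene_associated),
            ("Spontaneous", self.n_spontaneous),
            ("Exchange reactions", self.n_exchange),
            ("Metabolites", self.n_metabolites),
        ]
        width = max(len(k) for k, _ in rows)
        return "\n".join(f"{k:<{width}}  {v}" for k, v in rows)


def summarize_model(model: Model) -> ModelSummary:
    """Count genes/metabolites/reactions by kind and GPR presence.

    Gene-associated means an internal (non-spontaneous, non-exchange,
    non-objective) reaction with a non-empty GPR. The counts are invariant
    under reordering of the reaction list.
    """
    internal = [r for r in model.reactions
                if r.kind in (ReactionKind.INTERNAL, ReactionKind.SPONTANEOUS)]
    n_spont = sum(1 for r in internal if r.kind is ReactionKind.SPONTANEOUS)
    n_gene = sum(1 for r in internal
                 if r.kind is ReactionKind.INTERNAL and r.gpr is not None)
    n_non_gene = sum(1 for r in internal
                     if r.kind is ReactionKind.INTERNAL and r.gpr is None)
    return ModelSummary(
        n_genes=len(model.genes),
        n_metabolites=len(model.metabolites),
        n_reactions_total=len(internal),
        n_gene_associated=n_gene,
        n_non_gene_associated=n_non_gene,
        n_spontaneous=n_spont,
        n_exchange=sum(1 for r in model.reactions
                       if r.kind is ReactionKind.EXCHANGE),
    )


def validate_model(model: Model) -> List[str]:
    """Check every structural invariant; return human-readable violations.

    Violations are data, not exceptions: an empty list means the model is
    structurally valid. Each message names the offending entity and rule.
    """
    violations: List[str] = []
    met_ids = [m.id for m in model.metabolites]
    met_set = set(met_ids)
    if len(met_ids) != len(met_set):
        seen: set = set()
        for mid in met_ids:
            if mid in seen:
                violations.append(f"metabolite {mid!r}: duplicate id")
            seen.add(mid)
    for m in model.metabolites:
        if m.compartment not in COMPARTMENTS:
            violations.append(
                f"metabolite {m.id!r}: compartment {m.compartment!r} is not "
                f"one of {COMPARTMENTS}")

    rxn_ids = [r.id for r in model.reactions]
    if len(rxn_ids) != len(set(rxn_ids)):
        seen = set()
        for rid in rxn_ids:
            if rid in seen:
                violations.append(f"reaction {rid!r}: duplicate id")
            seen.add(rid)

    gene_set = set(model.genes)
    comp_of = {m.id: m.compartment for m in model.metabolites}
    for r in model.reactions:
        if not r.stoichiometry:
            violations.append(f"reaction {r.id!r}: empty stoichiometry")
        if r.lower_bound > r.upper_bound:
            violations.append(
                f"reaction {r.id!r}: lower_bound {r.lower_bound} > "
                f"upper_bound {r.upper_bound}")
        missing = sorted(set(r.stoichiometry) - met_set)
        for mid in missing:
            violations.append(
                f"reaction {r.id!r}: references undeclared metabolite {mid!r}")
        if r.kind is ReactionKind.EXCHANGE:
            if len(r.stoichiometry) != 1:
                violations.append(
                    f"reaction {r.id!r}: exchange reaction must touch exactly "
                    f"one metabolite (touches {len(r.stoichiometry)})")
            else:
                (mid,) = r.stoichiometry
                if comp_of.get(mid) == "c":
                    violations.append(
                        f"reaction {r.id!r}: exchange metabolite {mid!r} is "
                        f"not extracellular")
        for g in sorted(r.genes - gene_set):
            violations.append(
                f"reaction {r.id!r}: GPR cites gene {g!r} absent from the "
                f"model gene list")

    for rid in model.objective_reaction_ids:
        if rid not in set(rxn_ids):
            violations.append(
                f"objective reaction {rid!r} is not in the model")
    return violations


def assert_valid(model: Model) -> None:
    """Raise ``ValueError`` listing all violations if the model is invalid."""
    violations = validate_model(model)
    if violations:
        raise ValueError(
            f"model {model.id!r} failed validation:\n  "
            + "\n  ".join(violations))
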