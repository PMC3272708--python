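"""Native tabular model format: three TSV files in one directory.

* ``metabolites.tsv`` — id, name, compartment, formula
* ``reactions.tsv``   — id, name, equation, lb, ub, gpr, subsystem, kind
* ``genes.tsv``       — id

Equation strings use the ``[c]``/``[e]`` suffix convention and ``->`` for
irreversible, ``<=>`` for reversible reactions, e.g.::

    2 atp[c] + mal[c] -> g6p[c] + 2 adp[c]

The arrow is cosmetic on read: reversibility is taken from the bounds.
"""

from __future__ import annotations

import os
import re
from typing import Dict, List, Tuple

import pandas as pd

from .gpr import gpr_to_string
from .model import Metabolite, Model, Reaction, ReactionKind, assert_valid

_TERM_RE = re.compile(r"^(?:\(?([0-9.eE+-]+)\)?\s+)?(\S+)$")


def parse_equation(text: str) -> Dict[str, float]:
    """Parse ``a[c] + 2 b[c] -> c[c]`` into a signed stoichiometry map."""
    for arrow in ("<=>", "<->", "-->", "->", "="):
        if arrow in text:
            lhs, rhs = text.split(arrow, 1)
            break
    else:
        raise ValueError(f"no reaction arrow in equation {text!r}")
    stoich: Dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            term = term.strip()
            if not term:
                continue
            m = _TERM_RE.match(term)
            if m is None:
                raise ValueError(f"cannot parse equation term {term!r}")
            coef = float(m.group(1)) if m.group(1) else 1.0
            met = m.group(2)
            stoich[met] = stoich.get(met, 0.0) + sign * coef

    add_side(lhs, -1.0)
    add_side(rhs, +1.0)
    return {m: c for m, c in stoich.items() if c != 0}


def write_tabular_model(model: Model, directory: str) -> None:
    """Write the three-TSV native format (validates the model first)."""
    assert_valid(model)
    os.makedirs(directory, exist_ok=True)
    mets = pd.DataFrame(
        [(m.id, m.name, m.compartment, m.formula or "")
         for m in model.metabolites],
        columns=["id", "name", "compartment", "formula"])
    rxns = pd.DataFrame(
        [(r.id, r.name, r.equation(), r.lower_bound, r.upper_bound,
          gpr_to_string(r.gpr) if r.gpr is not None else "",
          r.subsystem or "", r.kind.value,
          "1" if r.id in model.objective_reaction_ids else "")
         for r in model.reactions],
        columns=["id", "name", "equation", "lb", "ub", "gpr", "subsystem",
                 "kind", "objective"])
    genes = pd.DataFrame({"id": list(model.genes)})
    mets.to_csv(os.path.join(directory, "metabolites.tsv"), sep="\t",
                index=False)
    rxns.to_csv(os.path.join(directory, "reactions.tsv"), sep="\t",
                index=False)
    genes.to_csv(os.path.join(directory, "genes.tsv"), sep="\t", index=False)


def read_tabular_model(directory: str, model_id: str = "model") -> Model:
    """Read the three-TSV native format back into a :class:`Model`."""
    mets = pd.read_csv(os.path.join(directory, "metabolites.tsv"), sep="\t",
                       dtype=str, keep_default_na=False)
    rxns = pd.read_csv(os.path.join(directory, "reactions.tsv"), sep="\t",
                       dtype=str, keep_default_na=False)
    genes_path = os.path.join(directory, "genes.tsv")
    genes: List[str] = []
    if os.path.exists(genes_path):
        gdf = pd.read_csv(genes_path, sep="\t", dtype=str,
                          keep_default_na=False)
        genes = [g for g in gdf["id"].tolist() if g]

    model = Model(id=model_id)
    for row in mets.itertuples(index=False):
        model.add_metabolite(Metabolite(
            id=row.id, name=row.name, compartment=row.compartment,
            formula=row.formula or None))
    objective: List[str] = []
    for row in rxns.itertuples(index=False):
        rxn = Reaction(
            id=row.id, name=row.name,
            stoichiometry=parse_equation(row.equation),
            lower_bound=float(row.lb), upper_bound=float(row.ub),
            gpr=row.gpr or None, subsystem=row.subsystem or None,
            kind=ReactionKind(row.kind))
        model.add_reaction(rxn)
        if getattr(row, "objective", "") == "1":
            objective.append(row.id)
    for g in genes:
        if g not in model.genes:
            model.genes.append(g)
    model.objective_reaction_ids = objective
    assert_valid(model)
    return model
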