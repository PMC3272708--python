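"""Single-gene-deletion screening for SNF-essential genes.

A gene is SNF-essential when deleting it (disabling every reaction whose
GPR evaluates false without it) drops the optimum of the nutrient-sharing
objective below ``threshold_fraction`` of the wild type — i.e. the mutant
bacteroid can no longer fix and export nitrogen at a meaningful rate. The
screen is exhaustive over the model's gene list and its outcome does not
depend on iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Set

import pandas as pd

from .fba import FluxSolution, solve_fba
from .gpr import reactions_disabled_by
from .model import Model

#: Deletion counts as essential below this fraction of the wild-type
#: optimum: 1% separates numerically-abolished from reduced-but-viable.
DEFAULT_THRESHOLD_FRACTION = 0.01


@dataclass
class GeneResult:
    gene: str
    wildtype_objective: float
    deletion_objective: float
    ratio: float
    verdict: str  # essential | non_essential


@dataclass
class EssentialityReport:
    threshold_fraction: float
    wildtype_objective: float
    results: List[GeneResult] = field(default_factory=list)

    @property
    def essential_genes(self) -> FrozenSet[str]:
        return frozenset(r.gene for r in self.results
                         if r.verdict == "essential")

    @property
    def n_essential(self) -> int:
        return len(self.essential_genes)

    @property
    def n_genes_screened(self) -> int:
        return len(self.results)

    @property
    def fraction_essential(self) -> float:
        if not self.results:
            return 0.0
        return self.n_essential / self.n_genes_screened

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.gene, r.wildtype_objective, r.deletion_objective, r.ratio,
              r.verdict) for r in self.results],
            columns=["gene", "wt_objective", "ko_objective", "ratio",
                     "verdict"])


def screen_essential_genes(model: Model,
                           threshold_fraction: float =
                           DEFAULT_THRESHOLD_FRACTION,
                           genes: Optional[List[str]] = None
                           ) -> EssentialityReport:
    """Delete each gene in turn, re-solve FBA and classify the outcome.

    Requires a model with the SNF objective and medium applied and a
    positive wild-type optimum (a bacteroid that cannot fix nitrogen at all
    cannot be screened). Deletions that make the LP infeasible count as
    objective zero. Results are ordered by gene id.
    """
    wt = solve_fba(model)
    if not wt.optimal or wt.objective_value <= 0:
        raise ValueError(
            "model cannot fix nitrogen before screening (wild-type optimum "
            f"is {wt.status}, value {wt.objective_value!r})")
    genes = sorted(model.genes if genes is None else genes)
    report = EssentialityReport(threshold_fraction=threshold_fraction,
                                wildtype_objective=wt.objective_value)
    for gene in genes:
        disabled = reactions_disabled_by(model, {gene})
        saved = {}
        for rid in disabled:
            rxn = model.reaction(rid)
            saved[rid] = (rxn.lower_bound, rxn.upper_bound)
            rxn.lower_bound = rxn.upper_bound = 0.0
        try:
            ko = solve_fba(model)
            ko_value = ko.objective_value if ko.optimal else 0.0
        finally:
            for rid, (lb, ub) in saved.items():
                rxn = model.reaction(rid)
                rxn.lower_bound, rxn.upper_bound = lb, ub
        ratio = ko_value / wt.objective_value
        verdict = ("essential" if ratio < threshold_fraction
                   else "non_essential")
        report.results.append(GeneResult(
            gene=gene, wildtype_objective=wt.objective_value,
            deletion_objective=ko_value, ratio=ratio, verdict=verdict))
    return report


@dataclass
class GeneSetComparison:
    """Venn-cell counts over a predicted set and up to two reference sets."""

    predicted: FrozenSet[str]
    references: Dict[str, FrozenSet[str]]
    cells: Dict[str, int] = field(default_factory=dict)
    membership: pd.DataFrame = field(default_factory=pd.DataFrame)


def compare_gene_sets(predicted: Set[str],
                      references: Mapping[str, Set[str]]
                      ) -> GeneSetComparison:
    """Venn decomposition of the predicted set against reference gene sets.

    Cell keys are '+'-joined sorted set names (e.g. ``predicted+DEG``); the
    cell counts partition the union, so they always sum to its size. Also
    returns a per-gene membership table for TSV export.
    """
    if len(references) > 2:
        raise ValueError("at most two reference sets are supported")
    sets: Dict[str, FrozenSet[str]] = {"predicted": frozenset(predicted)}
    for name, ref in references.items():
        if name == "predicted":
            raise ValueError("'predicted' is a reserved set name")
        sets[name] = frozenset(ref)

    union = frozenset().union(*sets.values()) if sets else frozenset()
    cells: Dict[str, int] = {}
    rows = []
    for gene in sorted(union):
        members = sorted(name for name, s in sets.items() if gene in s)
        key = "+".join(members)
        cells[key] = cells.get(key, 0) + 1
        rows.append((gene, *[gene in sets[n] for n in sets]))
    membership = pd.DataFrame(rows, columns=["gene", *sets])
    return GeneSetComparison(
        predicted=sets["predicted"],
        references={n: s for n, s in sets.items() if n != "predicted"},
        cells=cells, membership=membership)
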