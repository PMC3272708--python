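"""Network-gap detection: dead-end metabolites and blocked reactions.

Gaps drive annotation refinement during reconstruction: a metabolite that
no reaction can produce (or none can consume) indicates a missing enzyme
assignment, and every reaction forced to zero flux in the whole feasible
region is a candidate symptom of such a gap. Candidate fixes are reported
by joining gaps to reciprocal-best-hit evidence; edits are never applied
automatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .fba import flux_variability
from .model import Model
from .rbh import HitRecord, RbhCriteria, filter_rbh


@dataclass
class DeadEnd:
    metabolite_id: str
    kind: str  # no_production | no_consumption


@dataclass
class GapReport:
    dead_end_metabolites: List[DeadEnd] = field(default_factory=list)
    blocked_reactions: List[str] = field(default_factory=list)


def find_dead_end_metabolites(model: Model) -> GapReport:
    """Metabolites never producible (or never consumable) by bound-sign
    analysis, exchange reactions included.

    A reaction with coefficient ``c`` for metabolite ``m`` can produce m
    when ``c > 0`` and the upper bound allows forward flux, or ``c < 0``
    and the lower bound allows reverse flux; symmetrically for consumption.
    """
    producible = {m.id: False for m in model.metabolites}
    consumable = {m.id: False for m in model.metabolites}
    for rxn in model.reactions:
        fwd = rxn.upper_bound > 0
        rev = rxn.lower_bound < 0
        for met, coef in rxn.stoichiometry.items():
            if (coef > 0 and fwd) or (coef < 0 and rev):
                producible[met] = True
            if (coef < 0 and fwd) or (coef > 0 and rev):
                consumable[met] = True
    dead: List[DeadEnd] = []
    for m in model.metabolites:
        if not producible[m.id]:
            dead.append(DeadEnd(m.id, "no_production"))
        elif not consumable[m.id]:
            dead.append(DeadEnd(m.id, "no_consumption"))
    dead.sort(key=lambda d: d.metabolite_id)
    return GapReport(dead_end_metabolites=dead)


def find_blocked_reactions(model: Model, tolerance: float = 1e-9
                           ) -> List[str]:
    """Reactions whose max |flux| over the feasible region is <= tolerance.

    The objective is ignored (FVA at fraction 0); the scan is local in the
    sense that adding a disconnected reaction cannot unblock an existing
    one.
    """
    ranges = flux_variability(model, objective_fraction=0.0)
    blocked = [fr.reaction_id for fr in ranges
               if max(abs(fr.min_flux), abs(fr.max_flux)) <= tolerance]
    return sorted(blocked)


def gap_report(model: Model, tolerance: float = 1e-9) -> GapReport:
    """Full gap report: dead ends plus blocked reactions."""
    report = find_dead_end_metabolites(model)
    report.blocked_reactions = find_blocked_reactions(model, tolerance)
    return report


def refinement_candidates(report: GapReport,
                          forward: Sequence[HitRecord],
                          reverse: Sequence[HitRecord],
                          criteria: Optional[RbhCriteria] = None
                          ) -> List[Tuple[str, str, str]]:
    """Join gaps to RBH evidence: (gap entity, candidate gene, ortholog).

    Purely reportive — the caller decides whether a reciprocal best hit
    justifies re-annotating a gene to fill a gap.
    """
    pairs = filter_rbh(forward, reverse, criteria)
    out: List[Tuple[str, str, str]] = []
    for dead in report.dead_end_metabolites:
        for q, s in pairs:
            out.append((dead.metabolite_id, q, s))
    return out
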