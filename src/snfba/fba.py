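"""Flux balance analysis: steady-state LP, flux variability, pathway activity.

The feasible flux space is ``{v : S v = 0, lb <= v <= ub}`` where ``S`` is
the stoichiometric matrix. :func:`solve_fba` maximises the summed flux
through the model's objective reaction(s) with the HiGHS LP solver
(``scipy.optimize.linprog``). :func:`flux_variability` computes per-reaction
flux ranges at a fixed objective fraction and backs the pathway-activity
calls, which are therefore robust to alternate optima.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linprog

from .model import Model, ReactionKind

#: LP feasibility/optimality tolerance (documented, configurable per call).
LP_TOLERANCE = 1e-9

#: Flux magnitude below which a pathway is considered inactive (mmol/gDW/hr).
DEFAULT_EPSILON = 1e-6


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: Dict[str, float]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class FluxRange:
    reaction_id: str
    min_flux: float
    max_flux: float


@dataclass
class PathwayActivity:
    subsystem: str
    status: str  # active | inactive
    evidence: float  # max |flux| attainable over member reactions at optimum

    @property
    def active(self) -> bool:
        return self.status == "active"


class _CompiledModel:
    """S matrix plus bound vectors, with a stable reaction index."""

    def __init__(self, model: Model):
        self.reaction_ids = [r.id for r in model.reactions]
        met_index = {m.id: i for i, m in enumerate(model.metabolites)}
        n_m, n_r = len(model.metabolites), len(model.reactions)
        S = np.zeros((n_m, n_r))
        lb = np.zeros(n_r)
        ub = np.zeros(n_r)
        for j, rxn in enumerate(model.reactions):
            lb[j], ub[j] = rxn.lower_bound, rxn.upper_bound
            for met, coef in rxn.stoichiometry.items():
                S[met_index[met], j] += coef
        self.S, self.lb, self.ub = S, lb, ub
        self.index = {rid: j for j, rid in enumerate(self.reaction_ids)}

    def objective_vector(self, model: Model,
                         weights: Optional[Dict[str, float]] = None
                         ) -> np.ndarray:
        c = np.zeros(len(self.reaction_ids))
        if weights is None:
            weights = {rid: 1.0 for rid in model.objective_reaction_ids}
        for rid, w in weights.items():
            c[self.index[rid]] = w
        return c


def _solve_lp(c_max: np.ndarray, compiled: _CompiledModel,
              extra_A: Optional[np.ndarray] = None,
              extra_b: Optional[np.ndarray] = None,
              tolerance: float = LP_TOLERANCE):
    """Maximise ``c_max . v`` over the flux polytope (+ optional A v >= b)."""
    kwargs = dict(
        c=-c_max,
        A_eq=compiled.S,
        b_eq=np.zeros(compiled.S.shape[0]),
        bounds=list(zip(compiled.lb, compiled.ub)),
        method="highs",
        options={"presolve": True,
                 "primal_feasibility_tolerance": max(tolerance, 1e-10),
                 "dual_feasibility_tolerance": max(tolerance, 1e-10)},
    )
    if extra_A is not None:
        kwargs["A_ub"] = -extra_A  # A v >= b  ->  -A v <= -b
        kwargs["b_ub"] = -np.asarray(extra_b)
    return linprog(**kwargs)


def solve_fba(model: Model,
              objective_weights: Optional[Dict[str, float]] = None,
              tolerance: float = LP_TOLERANCE) -> FluxSolution:
    """Maximise flux through the model's objective pseudo-reaction(s).

    Returns status ``infeasible`` / ``unbounded`` faithfully instead of
    raising. ``objective_weights`` overrides the default unit weight on each
    id in ``model.objective_reaction_ids`` (used by the weighted-sum
    objective mode).
    """
    if objective_weights is None and not model.objective_reaction_ids:
        raise ValueError(
            f"model {model.id!r} has no objective reactions defined")
    compiled = _CompiledModel(model)
    c = compiled.objective_vector(model, objective_weights)
    res = _solve_lp(c, compiled, tolerance=tolerance)
    if res.status == 2:
        return FluxSolution("infeasible", float("nan"), {})
    if res.status == 3:
        return FluxSolution("unbounded", float("inf"), {})
    if not res.success:
        raise RuntimeError(f"LP solver failure: {res.message}")
    fluxes = dict(zip(compiled.reaction_ids, (float(x) for x in res.x)))
    return FluxSolution("optimal", float(-res.fun), fluxes)


def flux_variability(model: Model, objective_fraction: float = 1.0,
                     reaction_ids: Optional[Sequence[str]] = None,
                     tolerance: float = LP_TOLERANCE) -> List[FluxRange]:
    """Per-reaction min/max flux with objective >= fraction x optimum.

    ``objective_fraction`` must lie in [0, 1]; at 0 the objective is ignored
    entirely, which is the mode used for blocked-reaction detection.
    Propagates infeasibility of the wild-type problem as a ``ValueError``.
    """
    if not 0.0 <= objective_fraction <= 1.0:
        raise ValueError("objective_fraction must be in [0, 1]")
    compiled = _CompiledModel(model)
    extra_A = extra_b = None
    if model.objective_reaction_ids and objective_fraction > 0:
        base = solve_fba(model, tolerance=tolerance)
        if not base.optimal:
            raise ValueError(
                f"cannot run FVA: base FBA is {base.status}")
        c = compiled.objective_vector(model)
        # tiny slack keeps the constraint numerically feasible at fraction 1
        extra_A = c.reshape(1, -1)
        extra_b = np.array([objective_fraction * base.objective_value
                            - 1e-9 * max(1.0, abs(base.objective_value))])
    if reaction_ids is None:
        reaction_ids = compiled.reaction_ids
    ranges: List[FluxRange] = []
    for rid in reaction_ids:
        e = np.zeros(len(compiled.reaction_ids))
        e[compiled.index[rid]] = 1.0
        lo_res = _solve_lp(-e, compiled, extra_A, extra_b, tolerance)
        hi_res = _solve_lp(e, compiled, extra_A, extra_b, tolerance)
        if lo_res.status == 2 or hi_res.status == 2:
            raise ValueError("FVA subproblem infeasible")
        lo = float(lo_res.fun) if lo_res.success else -float("inf")
        hi = float(-hi_res.fun) if hi_res.success else float("inf")
        if lo > hi:  # numerical jitter on a fixed flux
            lo = hi = 0.5 * (lo + hi)
        ranges.append(FluxRange(rid, lo, hi))
    return ranges


def classify_pathway_activity(model: Model, epsilon: float = DEFAULT_EPSILON,
                              objective_fraction: float = 1.0
                              ) -> List[PathwayActivity]:
    """Call each subsystem active/inactive at the (fractional) optimum.

    A subsystem is *active* iff some member reaction can carry
    ``|flux| > epsilon`` while the objective stays at ``objective_fraction``
    of its optimum. Always uses FVA rather than a single flux vector, so the
    calls do not depend on which optimal vertex the solver returns.
    Exchange and objective pseudo-reactions are not classified.
    """
    members: Dict[str, List[str]] = {}
    for rxn in model.reactions:
        if rxn.kind in (ReactionKind.EXCHANGE, ReactionKind.OBJECTIVE_PSEUDO):
            continue
        if rxn.subsystem:
            members.setdefault(rxn.subsystem, []).append(rxn.id)
    all_ids = [rid for ids in members.values() for rid in ids]
    ranges = {fr.reaction_id: fr
              for fr in flux_variability(model, objective_fraction,
                                         reaction_ids=all_ids)}
    activities: List[PathwayActivity] = []
    for subsystem in sorted(members):
        evidence = max(max(abs(ranges[rid].min_flux),
                           abs(ranges[rid].max_flux))
                       for rid in members[subsystem])
        status = "active" if evidence > epsilon else "inactive"
        activities.append(PathwayActivity(subsystem, status, evidence))
    return activities


def mass_balance_residual(model: Model, solution: FluxSolution) -> float:
    """Max |S v| component for a solution; diagnostic for tests/reports."""
    compiled = _CompiledModel(model)
    v = np.array([solution.fluxes[rid] for rid in compiled.reaction_ids])
    return float(np.max(np.abs(compiled.S @ v))) if len(v) else 0.0
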