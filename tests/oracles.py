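"""Independent brute-force oracles used to cross-check the library.

These deliberately avoid the code paths they validate: the LP oracle
enumerates polytope vertices with plain linear algebra instead of calling a
solver, and the GPR oracle evaluates the serialised Boolean expression with
Python's own ``eval``.
"""

from itertools import combinations, product

import numpy as np

from snfba.fba import _CompiledModel
from snfba.gpr import gpr_to_string


def vertex_enumeration_max(model, tol=1e-8):
    """Max objective over {S v = 0, lb <= v <= ub} by vertex enumeration.

    Requires finite bounds. Every vertex fixes (n - rank(S)) fluxes at a
    bound and solves the remaining square-ish system; infeasible or
    rank-deficient combinations are skipped. The zero vector is always a
    feasible fallback candidate.
    """
    compiled = _CompiledModel(model)
    S, lb, ub = compiled.S, compiled.lb, compiled.ub
    if not (np.all(np.isfinite(lb)) and np.all(np.isfinite(ub))):
        raise ValueError("vertex oracle needs finite bounds")
    c = compiled.objective_vector(model)
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S)
    d = n - rank
    best = 0.0 if _feasible_zero(lb, ub) else None
    for fixed_idx in combinations(range(n), d):
        free_idx = [j for j in range(n) if j not in fixed_idx]
        A = S[:, free_idx]
        if np.linalg.matrix_rank(A) < len(free_idx):
            continue
        for choice in product(*[(lb[j], ub[j]) for j in fixed_idx]):
            rhs = -S[:, fixed_idx] @ np.array(choice)
            sol, residual, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            if np.max(np.abs(A @ sol - rhs)) > tol:
                continue
            v = np.zeros(n)
            v[list(fixed_idx)] = choice
            v[free_idx] = sol
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            value = float(c @ v)
            if best is None or value > best:
                best = value
    if best is None:
        raise ValueError("no feasible vertex found")
    return best


def _feasible_zero(lb, ub):
    return bool(np.all(lb <= 0) and np.all(ub >= 0))


def truth_table_eval(tree, deleted):
    """Evaluate a GPR by eval-ing its serialised Boolean expression."""
    expr = gpr_to_string(tree)
    genes = set()
    _collect(tree, genes)
    env = {g: (g not in deleted) for g in genes}
    return bool(eval(expr, {"__builtins__": {}}, env))


def _collect(tree, out):
    from snfba.gpr import Gene
    if isinstance(tree, Gene):
        out.add(tree.gene)
    else:
        for child in tree.children:
            _collect(child, out)


def naive_homolog_scan(hits, max_e, min_identity):
    """Row-by-row reference implementation of the homolog filter."""
    kept = []
    for h in hits:
        if h.e_value < max_e and h.percent_identity > min_identity:
            if h.query not in kept:
                kept.append(h.query)
    return sorted(kept)
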