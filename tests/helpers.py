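"""Independent oracles used to cross-check the LP engine.

The brute-force oracle enumerates candidate vertices of the flux polytope
{S v = 0, lb <= v <= ub} by fixing every size-d subset of variables at a
bound (d = n - rank(S)) and solving the remaining square-ish linear system.
It shares no code path with the scipy/HiGHS engine.
"""

from __future__ import annotations

import itertools

import numpy as np

from methanoflux.model_core import MetabolicModel, stoichiometric_matrix

FEAS_TOL = 1e-8


def brute_force_fba_max(model: MetabolicModel, objective_id: str) -> float | None:
    """Max objective flux over enumerated basic feasible solutions.

    Returns None if no feasible vertex exists.  Only for tiny models
    (<= ~10 reactions).
    """
    S = stoichiometric_matrix(model).toarray()
    m, n = S.shape
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    j_obj = model.reaction_ids.index(objective_id)
    rank = np.linalg.matrix_rank(S, tol=1e-10)
    d = n - rank

    best: float | None = None

    def consider(v: np.ndarray) -> None:
        nonlocal best
        if np.max(np.abs(S @ v)) > FEAS_TOL:
            return
        if np.any(v < lb - FEAS_TOL) or np.any(v > ub + FEAS_TOL):
            return
        val = float(v[j_obj])
        if best is None or val > best:
            best = val

    if d == 0:
        sol, *_ = np.linalg.lstsq(S, np.zeros(m), rcond=None)
        consider(sol)
        return best

    for fixed in itertools.combinations(range(n), d):
        free = [j for j in range(n) if j not in fixed]
        A = S[:, free]
        for bounds_choice in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
            rhs = -S[:, fixed] @ np.array(bounds_choice)
            sol, residuals, rk, _ = np.linalg.lstsq(A, rhs, rcond=None)
            if rk < len(free):
                continue  # underdetermined: not a vertex for this choice
            v = np.empty(n)
            v[list(fixed)] = bounds_choice
            v[free] = sol
            consider(v)
    return best
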