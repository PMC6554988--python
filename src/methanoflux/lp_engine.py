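"""Linear-programming core: FBA, parsimonious FBA, FVA, essentiality, Pareto sweeps.

All entry points reduce to one "solve LP" contract (:func:`solve_lp`), so the
backend is pluggable; the default backend is scipy's HiGHS interface.  Flux
balance analysis maximises (or minimises) one reaction flux subject to the
steady-state constraint S v = 0 and the model's flux bounds:

    max  c' v   s.t.   S v = 0,   lb <= v <= ub

Individual flux values at an FBA optimum are generally non-unique; whenever a
single representative flux vector is reported downstream, it comes from
parsimonious FBA (:func:`pfba`), which minimises total absolute flux subject
to near-optimality of the objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model_core import MetabolicModel, stoichiometric_matrix

__all__ = [
    "FluxSolution",
    "ParetoPoint",
    "solve_lp",
    "fba",
    "pfba",
    "fva",
    "essential_reactions",
    "pareto_sweep",
    "FEASIBILITY_TOL",
    "BALANCE_TOL",
    "ESSENTIALITY_THRESHOLD",
    "PFBA_RELATIVE_EPS",
]

#: LP feasibility/optimality tolerance passed to the solver.
FEASIBILITY_TOL = 1e-9
#: Tolerance for post-hoc mass-balance checks |S v| <= tol.
BALANCE_TOL = 1e-6
#: Knockout optimum below this fraction of wild type counts as "no growth".
ESSENTIALITY_THRESHOLD = 1e-6
#: pfba keeps the objective within (1 - eps) of the FBA optimum.
PFBA_RELATIVE_EPS = 1e-6

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"


@dataclass
class FluxSolution:
    """Outcome of an FBA-type optimisation.

    ``objective_value`` is in the units of the objective reaction (h^-1 for
    biomass, mmol g-DW^-1 h^-1 otherwise); ``fluxes`` is empty unless
    ``status == "optimal"``.
    """

    status: str
    objective_value: float | None = None
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == OPTIMAL

    def flux(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]


@dataclass
class ParetoPoint:
    """One point of a two-objective trade-off curve.

    ``forced_product`` and ``acceptor_consumed`` are in mol per mol of
    substrate (PHB in the anoxic scenarios); ``max_objective`` is the
    constrained optimum (mol ATP per mol PHB).
    """

    forced_product: float
    max_objective: float | None
    acceptor_consumed: float | None
    feasible: bool = True


# ---------------------------------------------------------------------------
# Backend
# ---------------------------------------------------------------------------

def solve_lp(
    c: np.ndarray,
    A_eq: sparse.spmatrix,
    b_eq: np.ndarray,
    bounds: Sequence[tuple[float, float]],
    A_ub: sparse.spmatrix | None = None,
    b_ub: np.ndarray | None = None,
) -> tuple[str, float | None, np.ndarray | None]:
    """Minimise ``c' x`` subject to ``A_eq x = b_eq``, ``A_ub x <= b_ub`` and bounds.

    Returns ``(status, objective, x)`` with status one of "optimal",
    "infeasible", "unbounded".  This is the single solver contract behind
    every other operation in the module.
    """
    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=b_eq,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=list(bounds),
        method="highs",
        options={"primal_feasibility_tolerance": FEASIBILITY_TOL,
                 "dual_feasibility_tolerance": FEASIBILITY_TOL},
    )
    if res.status == 0:
        return OPTIMAL, float(res.fun), np.asarray(res.x)
    if res.status == 2:
        return INFEASIBLE, None, None
    if res.status == 3:
        return UNBOUNDED, None, None
    # numerical trouble: report as infeasible rather than raising
    return INFEASIBLE, None, None


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------

def _effective_bounds(
    model: MetabolicModel,
    extra_bounds: Mapping[str, tuple[float, float]] | None,
) -> list[tuple[float, float]]:
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    if extra_bounds:
        pos = {r.id: i for i, r in enumerate(model.reactions)}
        for rid, (lb, ub) in extra_bounds.items():
            if rid not in pos:
                raise KeyError(f"extra_bounds names unknown reaction {rid!r}")
            if lb > ub:
                raise ValueError(f"extra_bounds for {rid}: lb {lb} > ub {ub}")
            bounds[pos[rid]] = (lb, ub)
    return bounds


def fba(
    model: MetabolicModel,
    objective_id: str | None = None,
    sense: str = "maximize",
    extra_bounds: Mapping[str, tuple[float, float]] | None = None,
) -> FluxSolution:
    """Flux balance analysis: optimise one reaction flux at steady state.

    The objective value is deterministic for a fixed model; the returned flux
    vector is one of possibly many alternative optima (use :func:`pfba` when
    individual fluxes matter).
    """
    objective_id = objective_id or model.objective_id
    if objective_id is None:
        raise ValueError("no objective reaction given and model has none set")
    if not model.has_reaction(objective_id):
        raise KeyError(f"objective reaction {objective_id!r} not in model")
    if sense not in ("maximize", "minimize"):
        raise ValueError(f"sense must be 'maximize' or 'minimize', got {sense!r}")

    S = stoichiometric_matrix(model)
    n = len(model.reactions)
    bounds = _effective_bounds(model, extra_bounds)
    c = np.zeros(n)
    j = model.reaction_ids.index(objective_id)
    c[j] = -1.0 if sense == "maximize" else 1.0

    status, fun, x = solve_lp(c, S, np.zeros(S.shape[0]), bounds)
    if status != OPTIMAL:
        return FluxSolution(status=status)
    obj = -fun if sense == "maximize" else fun
    return FluxSolution(
        status=OPTIMAL,
        objective_value=obj,
        fluxes=dict(zip(model.reaction_ids, x)),
    )


# ---------------------------------------------------------------------------
# Parsimonious FBA
# ---------------------------------------------------------------------------

def pfba(
    model: MetabolicModel,
    objective_id: str | None = None,
    sense: str = "maximize",
    extra_bounds: Mapping[str, tuple[float, float]] | None = None,
    relative_eps: float = PFBA_RELATIVE_EPS,
) -> FluxSolution:
    """Parsimonious FBA: minimal total absolute flux at (1 - eps) optimality.

    Each reaction flux is split into two non-negative halves v = v+ - v-,
    sum(v+ + v-) is minimised subject to the original constraints plus the
    requirement that the objective stays within ``relative_eps`` (relative)
    of the plain FBA optimum.  The reported ``objective_value`` is the
    constrained FBA optimum; futile cycles carry zero flux in the result.
    """
    base = fba(model, objective_id, sense, extra_bounds)
    if not base.ok:
        return base
    opt = base.objective_value
    objective_id = objective_id or model.objective_id

    S = stoichiometric_matrix(model)
    m, n = S.shape
    bounds = _effective_bounds(model, extra_bounds)
    j = model.reaction_ids.index(objective_id)

    # variables [v+, v-]; v = v+ - v-
    S2 = sparse.hstack([S, -S], format="csc")
    split_bounds: list[tuple[float, float]] = []
    for lb, ub in bounds:
        split_bounds.append((max(lb, 0.0), max(ub, 0.0)))  # v+
    for lb, ub in bounds:
        split_bounds.append((max(-ub, 0.0), max(-lb, 0.0)))  # v-
    c = np.ones(2 * n)

    # objective constraint: c_obj' v >= / <= bound, as an A_ub row over (v+, v-)
    row = np.zeros(2 * n)
    row[j], row[n + j] = 1.0, -1.0
    slack = abs(opt) * relative_eps + 1e-12
    if sense == "maximize":
        A_ub = sparse.csr_matrix(-row)          # -(v_j) <= -(opt - slack)
        b_ub = np.array([-(opt - slack)])
    else:
        A_ub = sparse.csr_matrix(row)           # v_j <= opt + slack
        b_ub = np.array([opt + slack])

    status, fun, x = solve_lp(c, S2, np.zeros(m), split_bounds, A_ub=A_ub, b_ub=b_ub)
    if status != OPTIMAL:
        # fall back to the raw FBA vector (should not normally happen)
        return base
    v = x[:n] - x[n:]
    return FluxSolution(
        status=OPTIMAL,
        objective_value=opt,
        fluxes=dict(zip(model.reaction_ids, v)),
    )


# ---------------------------------------------------------------------------
# FVA
# ---------------------------------------------------------------------------

def fva(
    model: MetabolicModel,
    objective_id: str | None = None,
    fraction: float = 1.0,
    extra_bounds: Mapping[str, tuple[float, float]] | None = None,
    reactions: Iterable[str] | None = None,
) -> dict[str, tuple[float, float]]:
    """Flux variability analysis at ``objective >= fraction * optimum``.

    Returns per reaction the attainable (min, max) flux subject to the
    steady state, the bounds and near-optimality of the objective.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    objective_id = objective_id or model.objective_id
    base = fba(model, objective_id, "maximize", extra_bounds)
    if not base.ok:
        raise RuntimeError(f"FVA requires an FBA optimum; status = {base.status}")
    opt = base.objective_value

    S = stoichiometric_matrix(model)
    m, n = S.shape
    bounds = _effective_bounds(model, extra_bounds)
    j = model.reaction_ids.index(objective_id)

    # objective >= fraction * opt  (opt may be negative; the inequality keeps
    # the same orientation because fraction <= 1 relaxes toward feasibility)
    floor = fraction * opt if opt >= 0 else opt - (1.0 - fraction) * abs(opt)
    row = np.zeros(n)
    row[j] = -1.0
    A_ub = sparse.csr_matrix(row)
    b_ub = np.array([-floor + 1e-9])

    targets = list(reactions) if reactions is not None else model.reaction_ids
    pos = {r: i for i, r in enumerate(model.reaction_ids)}
    out: dict[str, tuple[float, float]] = {}
    zeros = np.zeros(m)
    for rid in targets:
        k = pos[rid]
        c = np.zeros(n)
        c[k] = 1.0
        _, lo, _ = solve_lp(c, S, zeros, bounds, A_ub=A_ub, b_ub=b_ub)
        c[k] = -1.0
        _, hi_neg, _ = solve_lp(c, S, zeros, bounds, A_ub=A_ub, b_ub=b_ub)
        lo = lo if lo is not None else bounds[k][0]
        hi = -hi_neg if hi_neg is not None else bounds[k][1]
        if lo > hi:  # numerical jitter around a fixed flux
            lo = hi = 0.5 * (lo + hi)
        out[rid] = (lo, hi)
    return out


# ---------------------------------------------------------------------------
# Essentiality
# ---------------------------------------------------------------------------

def essential_reactions(
    model: MetabolicModel,
    objective_id: str | None = None,
    threshold: float = ESSENTIALITY_THRESHOLD,
    extra_bounds: Mapping[str, tuple[float, float]] | None = None,
) -> set[str]:
    """Reactions whose single knockout abolishes growth.

    A reaction is essential iff forcing its flux to zero drops the optimum
    below ``threshold`` times the wild-type optimum.  Raises if the wild
    type itself cannot grow (essentiality is then undefined).
    """
    objective_id = objective_id or model.objective_id
    wt = fba(model, objective_id, "maximize", extra_bounds)
    if not wt.ok or wt.objective_value <= 0:
        raise RuntimeError(
            "wild-type optimum is zero or infeasible; essentiality undefined"
        )
    cutoff = threshold * wt.objective_value
    essential: set[str] = set()
    for r in model.reactions:
        ko = dict(extra_bounds) if extra_bounds else {}
        ko[r.id] = (0.0, 0.0)
        sol = fba(model, objective_id, "maximize", ko)
        if not sol.ok or sol.objective_value < cutoff:
            essential.add(r.id)
    return essential


# ---------------------------------------------------------------------------
# Pareto sweeps
# ---------------------------------------------------------------------------

def product_maximum(
    model: MetabolicModel,
    product_exchange_id: str,
    extra_bounds: Mapping[str, tuple[float, float]] | None = None,
) -> float:
    """Stoichiometric maximum of product secretion under the given constraints."""
    sol = fba(model, product_exchange_id, "maximize", extra_bounds)
    if not sol.ok:
        return 0.0
    return max(sol.objective_value, 0.0)


def default_grid(maximum: float, n_points: int = 21) -> list[float]:
    """Evenly spaced forced-product grid from 0 to the stoichiometric maximum."""
    return list(np.linspace(0.0, maximum, n_points))


def pareto_sweep(
    model: MetabolicModel,
    objective_id: str,
    product_exchange_id: str,
    grid: Sequence[float] | None = None,
    acceptor_exchange_id: str | None = None,
    extra_bounds: Mapping[str, tuple[float, float]] | None = None,
) -> list[ParetoPoint]:
    """Trade-off curve: maximise ``objective_id`` at each forced product level.

    For each grid value g, product secretion is fixed to g, the objective is
    maximised, and the acceptor consumption (absolute exchange flux, from the
    parsimonious solution) is recorded.  Infeasible grid points are returned
    flagged, never dropped.  With ``grid=None`` a 21-point grid from 0 to the
    product's stoichiometric maximum is used.
    """
    if grid is None:
        grid = default_grid(product_maximum(model, product_exchange_id, extra_bounds))
    points: list[ParetoPoint] = []
    for g in grid:
        if g < 0:
            raise ValueError("forced product amounts must be non-negative")
        eb = dict(extra_bounds) if extra_bounds else {}
        eb[product_exchange_id] = (g, g)
        sol = pfba(model, objective_id, "maximize", eb)
        if not sol.ok:
            points.append(ParetoPoint(g, None, None, feasible=False))
            continue
        acceptor = None
        if acceptor_exchange_id is not None:
            acceptor = abs(sol.flux(acceptor_exchange_id))
        points.append(ParetoPoint(g, sol.objective_value, acceptor))
    return points
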