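"""The four in-silico experiments as pipeline stages.

1. Methane growth: doubling-time/maintenance arithmetic and yield
   prediction (see also :mod:`methanoflux.mechanisms`).
2. Methane-PHB co-consumption: bottle totals fed directly as flux-scale
   quantities (valid by LP linearity and time invariance), plus a
   rates-mode flux-pattern comparison against growth on methane alone.
3. Anoxic PHB with denitrification: maintenance-ATP maximisation and
   overflow-product Pareto sweeps.
4. Network statistics: metabolite degree distributions with a power-law
   fit, and multi-model Venn comparison by stoichiometric signature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import constants
from .model_core import MetabolicModel, stoichiometric_matrix
from .lp_engine import fba, pfba, fva, pareto_sweep, product_maximum, ParetoPoint, FluxSolution
from .mechanisms import ReactionIdMap, MechanismVariant, apply_mechanism

__all__ = [
    "BottleExperiment",
    "DegreeDistribution",
    "CoConsumptionResult",
    "growth_rate_from_doubling_time",
    "maintenance_from_endogenous_respiration",
    "phb_amount_from_concentrations",
    "co_consumption",
    "anaplerosis_comparison",
    "anoxic_phb_atp",
    "anoxic_overflow_pareto",
    "degree_distribution",
    "compare_models",
    "ModelComparison",
]


# ---------------------------------------------------------------------------
# Desk arithmetic on the measured quantities
# ---------------------------------------------------------------------------

def growth_rate_from_doubling_time(td: float) -> float:
    """Specific growth rate mu = ln 2 / td (td in h, mu in h^-1)."""
    if td <= 0:
        raise ValueError("doubling time must be positive")
    return math.log(2.0) / td


def maintenance_from_endogenous_respiration(q_o2: float, atp_per_o2: float) -> float:
    """Non-growth maintenance ATP demand from endogenous respiration.

    ``ngam = q_o2 * atp_per_o2`` in mmol ATP g-DW^-1 h^-1, assuming the
    stated coupling of ATP synthesis to oxygen consumption.
    """
    if q_o2 < 0:
        raise ValueError("respiration rate must be non-negative")
    if atp_per_o2 <= 0:
        raise ValueError("atp_per_o2 must be positive")
    return q_o2 * atp_per_o2


def phb_amount_from_concentrations(
    c_initial: float, c_final: float, volume: float,
    monomer_mass: float = constants.PHB_MONOMER_MASS,
) -> float:
    """mmol of PHB monomer equivalents consumed in a bottle.

    ``(c_initial - c_final) g/L x volume L / monomer_mass g/mol``, with the
    monomer-equivalent molar mass equal to 3-hydroxybutyrate minus one
    water (86.09 g/mol).
    """
    if c_final < 0 or c_initial < c_final:
        raise ValueError("need c_initial >= c_final >= 0 (negative consumption)")
    if volume <= 0:
        raise ValueError("volume must be positive")
    return (c_initial - c_final) * volume / monomer_mass * 1000.0


# ---------------------------------------------------------------------------
# Co-consumption of methane and PHB
# ---------------------------------------------------------------------------

@dataclass
class BottleExperiment:
    """Totals of a closed-bottle methane/PHB co-consumption experiment."""

    liquid_volume: float = constants.BOTTLE_LIQUID_VOLUME_L  # L
    ch4_consumed: float = constants.BOTTLE_CH4_MMOL          # mmol per bottle
    phb_consumed: float = 0.0                                # mmol per bottle
    duration: float = constants.BOTTLE_DURATION_H            # h
    o2_consumed: float | None = None                         # mmol per bottle
    biomass_formed: float | None = None                      # mg non-PHB DW

    def __post_init__(self) -> None:
        if self.liquid_volume <= 0:
            raise ValueError("liquid_volume must be positive")
        for name in ("ch4_consumed", "phb_consumed", "duration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class CoConsumptionResult:
    status: str
    biomass_mg: float
    o2_mmol: float
    fluxes: dict[str, float]
    key_fluxes: dict[str, float]


_KEY_FLUX_ROLES = (
    "glycine_synthase",
    "malyl_coa_lyase",
    "methylmalyl_coa_lyase",
    "propionyl_coa_carboxylase",
    "phb_degradation",
)


def _key_fluxes(sol: FluxSolution, idmap: ReactionIdMap) -> dict[str, float]:
    out = {}
    for role in _KEY_FLUX_ROLES:
        rid = getattr(idmap, role)
        if rid in sol.fluxes:
            out[role] = sol.flux(rid)
    return out


def co_consumption(
    model: MetabolicModel,
    expt: BottleExperiment,
    variant: MechanismVariant | None = None,
    idmap: ReactionIdMap | None = None,
    charge_ngam: bool = False,
    ngam_atp: float = constants.NGAM_ATP,
) -> CoConsumptionResult:
    """Predict biomass and O2 for a closed-bottle co-consumption experiment.

    The bottle totals are used directly as flux-scale quantities: methane
    uptake is fixed at ``ch4_consumed``, the PHB-degradation entry flux at
    ``phb_consumed``, and biomass is maximised; predicted biomass in mg is
    the objective x 1000 and O2 is read off the exchange flux of the
    parsimonious solution.  Maintenance is excluded by default in this
    totals mode; ``charge_ngam=True`` charges ``ngam x duration x mean
    biomass`` (trapezoidal in the initial/final bottle concentrations) as a
    sensitivity run.
    """
    idmap = idmap or ReactionIdMap()
    m = apply_mechanism(model, variant) if variant is not None else model
    if not m.has_reaction(idmap.phb_degradation):
        raise KeyError(f"model lacks a PHB-degradation entry reaction "
                       f"({idmap.phb_degradation!r})")
    eb: dict[str, tuple[float, float]] = {
        idmap.ex_ch4: (-expt.ch4_consumed, -expt.ch4_consumed),
        idmap.ex_phb: (-expt.phb_consumed, 0.0),
        idmap.phb_degradation: (expt.phb_consumed, expt.phb_consumed),
    }
    if charge_ngam:
        mean_biomass_g = 0.5 * (
            constants.BOTTLE_BIOMASS_INITIAL_G_L + constants.BOTTLE_BIOMASS_FINAL_G_L
        ) * expt.liquid_volume
        total_atp = ngam_atp * expt.duration * mean_biomass_g
        eb[idmap.atp_maintenance] = (total_atp, total_atp)
    else:
        eb[idmap.atp_maintenance] = (0.0, 1000.0)
    sol = pfba(m, idmap.biomass, "maximize", eb)
    if not sol.ok:
        return CoConsumptionResult(sol.status, 0.0, 0.0, {}, {})
    return CoConsumptionResult(
        status=sol.status,
        biomass_mg=1000.0 * sol.objective_value,
        o2_mmol=abs(sol.flux(idmap.ex_o2)),
        fluxes=sol.fluxes,
        key_fluxes=_key_fluxes(sol, idmap),
    )


def anaplerosis_comparison(
    model: MetabolicModel,
    variant: MechanismVariant | None = None,
    idmap: ReactionIdMap | None = None,
    uptake_ch4_alone: float = constants.CH4_UPTAKE,
    uptake_ch4_cocons: float = 13.2,
    phb_rate: float = 0.608,
    ngam_atp: float = constants.NGAM_ATP,
) -> dict[str, dict[str, float]]:
    """Specific-rate flux patterns: growth on methane vs methane+PHB.

    Runs two parsimonious optimisations at per-gram-biomass rates — methane
    alone, and methane plus a fixed PHB-degradation rate — and reports the
    key anaplerotic fluxes of each (glycine synthase, both malyl-CoA lyase
    activities, propionyl-CoA carboxylation, PHB degradation) together with
    the growth rate.  PHB degradation displaces glycine synthase because
    glyoxylate from l-erythro-3-methylmalyl-CoA cleavage replenishes the
    serine cycle directly.
    """
    idmap = idmap or ReactionIdMap()
    m = apply_mechanism(model, variant) if variant is not None else model

    def run(uptake: float, phb: float) -> dict[str, float]:
        eb = {
            idmap.ex_ch4: (-uptake, -uptake),
            idmap.atp_maintenance: (ngam_atp, ngam_atp),
            idmap.ex_phb: (-phb, 0.0),
            idmap.phb_degradation: (phb, phb),
        }
        sol = pfba(m, idmap.biomass, "maximize", eb)
        if not sol.ok:
            raise RuntimeError(f"infeasible at uptake={uptake}, phb={phb}")
        out = _key_fluxes(sol, idmap)
        out["growth_rate"] = sol.objective_value
        out["ch4_uptake"] = abs(sol.flux(idmap.ex_ch4))
        return out

    return {
        "methane_only": run(uptake_ch4_alone, 0.0),
        "co_consumption": run(uptake_ch4_cocons, phb_rate),
    }


# ---------------------------------------------------------------------------
# Anoxic PHB / denitrification
# ---------------------------------------------------------------------------

def _anoxic_bounds(idmap: ReactionIdMap, phb: float, allow_nitrate: bool):
    return {
        idmap.ex_o2: (0.0, 0.0),
        idmap.ex_ch4: (0.0, 0.0),
        idmap.ex_phb: (-phb, 0.0),
        idmap.phb_degradation: (phb, phb),
        idmap.atp_maintenance: (0.0, 1000.0),
        idmap.ex_no3: (-1000.0, 0.0) if allow_nitrate else (0.0, 0.0),
    }


def anoxic_phb_atp(
    model: MetabolicModel,
    phb: float = 1.0,
    allow_nitrate: bool = True,
    idmap: ReactionIdMap | None = None,
) -> tuple[float, bool]:
    """Maximal maintenance-ATP from PHB with oxygen shut off.

    Returns ``(atp, feasible)`` in mol ATP per mol PHB.  With nitrate
    closed the network has no terminal electron acceptor and the forced
    PHB-degradation flux is infeasible; this is reported as ``(0.0,
    False)`` — the model predicts no fermentative ATP from PHB.
    """
    idmap = idmap or ReactionIdMap()
    sol = fba(model, idmap.atp_maintenance, "maximize",
              _anoxic_bounds(idmap, phb, allow_nitrate))
    if not sol.ok:
        return 0.0, False
    return sol.objective_value, True


def anoxic_overflow_pareto(
    model: MetabolicModel,
    product: str = "acetate",
    grid: Sequence[float] | None = None,
    idmap: ReactionIdMap | None = None,
    n_points: int = 21,
) -> list[ParetoPoint]:
    """ATP/nitrate trade-off versus forced overflow-product secretion.

    PHB degradation is fixed at 1 mol, oxygen at zero and nitrate open; for
    each forced secretion level of acetate or butane-2,3-diol the
    maintenance-ATP optimum and the nitrate consumed are recorded.  The
    default grid spans 0 to the product's stoichiometric maximum in
    ``n_points`` even steps.
    """
    idmap = idmap or ReactionIdMap()
    if product == "acetate":
        ex_prod, ex_other = idmap.ex_acetate, idmap.ex_butanediol
    elif product in ("butanediol", "butane-2,3-diol"):
        ex_prod, ex_other = idmap.ex_butanediol, idmap.ex_acetate
    else:
        raise ValueError(f"product must be 'acetate' or 'butanediol', got {product!r}")
    eb = _anoxic_bounds(idmap, 1.0, allow_nitrate=True)
    eb[ex_other] = (0.0, 0.0)  # isolate one product axis as in the trade-off plots
    if grid is None:
        grid = list(np.linspace(0.0, product_maximum(model, ex_prod, eb), n_points))
    return pareto_sweep(model, idmap.atp_maintenance, ex_prod, grid,
                        acceptor_exchange_id=idmap.ex_no3, extra_bounds=eb)


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

@dataclass
class DegreeDistribution:
    """Metabolite-connectivity histogram with a fitted power-law slope."""

    counts: dict[int, int]
    fitted_slope: float
    fitted_intercept: float
    excluded_hubs: list[str]
    single_point: bool = False

    @property
    def n_connected(self) -> int:
        return sum(self.counts.values())


def degree_distribution(
    model: MetabolicModel,
    active_only: bool = False,
    fva_result: Mapping[str, tuple[float, float]] | None = None,
    hub_percentile: float = 99.0,
    flux_tol: float = 1e-6,
) -> DegreeDistribution:
    """Distribution of the number of reactions each metabolite takes part in.

    The slope of log10 n(k) against log10 k is fitted by ordinary least
    squares over all degrees with n(k) >= 1, after excluding metabolites
    above the ``hub_percentile`` of the degree distribution (highly
    connected co-factors such as ATP and NADH sit above the power law and
    are reported in ``excluded_hubs``).  With ``active_only`` the degree
    counts only reactions that can carry flux at the growth optimum, as
    judged by a supplied flux-variability result at fraction 1.
    """
    if not model.metabolites or not model.reactions:
        raise ValueError("empty model")
    if active_only:
        if fva_result is None:
            fva_result = fva(model, fraction=1.0)
        active = {rid for rid, (lo, hi) in fva_result.items()
                  if max(abs(lo), abs(hi)) > flux_tol}
    else:
        active = set(model.reaction_ids)

    degrees: dict[str, int] = {}
    for rxn in model.reactions:
        if rxn.id not in active:
            continue
        for met_id in rxn.stoichiometry:
            degrees[met_id] = degrees.get(met_id, 0) + 1
    if not degrees:
        raise ValueError("no connected metabolites")

    values = np.array(list(degrees.values()), dtype=float)
    cutoff = np.percentile(values, hub_percentile)
    excluded = sorted(m for m, k in degrees.items() if k > cutoff)
    kept = {m: k for m, k in degrees.items() if k <= cutoff}

    counts: dict[int, int] = {}
    for k in kept.values():
        counts[k] = counts.get(k, 0) + 1
    ks = np.array(sorted(counts), dtype=float)
    ns = np.array([counts[int(k)] for k in ks], dtype=float)
    if len(ks) < 2:
        return DegreeDistribution(
            counts={int(k): int(counts[int(k)]) for k in ks},
            fitted_slope=float("nan"), fitted_intercept=float("nan"),
            excluded_hubs=excluded, single_point=True,
        )
    slope, intercept = np.polyfit(np.log10(ks), np.log10(ns), 1)
    return DegreeDistribution(
        counts={int(k): int(v) for k, v in zip(ks, ns)},
        fitted_slope=float(slope), fitted_intercept=float(intercept),
        excluded_hubs=excluded,
    )


# ---------------------------------------------------------------------------
# Multi-model comparison
# ---------------------------------------------------------------------------

_COMPARTMENT_STRIP = ("_c0", "_e0", "_p0")


def _strip_compartment(met_id: str) -> str:
    for suf in _COMPARTMENT_STRIP:
        if met_id.endswith(suf):
            return met_id[: -len(suf)]
    return met_id


def _reaction_signature(stoich: Mapping[str, float]) -> tuple:
    """Canonical, direction-invariant stoichiometric signature."""
    items = tuple(sorted(
        (_strip_compartment(m), round(c, 6)) for m, c in stoich.items()
    ))
    flipped = tuple(sorted(
        (_strip_compartment(m), round(-c, 6)) for m, c in stoich.items()
    ))
    return min(items, flipped)


@dataclass
class ModelComparison:
    """Venn-partition counts for >= 2 models."""

    model_ids: list[str]
    reaction_regions: dict[frozenset, int] = field(default_factory=dict)
    metabolite_regions: dict[frozenset, int] = field(default_factory=dict)
    id_match_reaction_regions: dict[frozenset, int] = field(default_factory=dict)

    def region(self, *model_ids: str) -> int:
        """Count of reactions present in exactly the given models."""
        return self.reaction_regions.get(frozenset(model_ids), 0)

    def unique_reactions(self, model_id: str) -> int:
        return self.region(model_id)

    def shared_reactions(self) -> int:
        return self.reaction_regions.get(frozenset(self.model_ids), 0)


def compare_models(models: Sequence[MetabolicModel]) -> ModelComparison:
    """Shared/unique reaction and metabolite counts per Venn region.

    Reactions are matched by canonical stoichiometric signature (sorted
    coefficient multiset over compartment-stripped metabolite ids,
    direction-invariant) so that independently reconstructed models with
    different id spellings still compare; an exact-id matching is included
    as a fallback report.  All region counts sum to the union size.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 models to compare")
    ids = [m.id for m in models]
    if len(set(ids)) != len(ids):
        raise ValueError("models must have distinct ids")

    def regions(member_sets: dict) -> dict[frozenset, int]:
        out: dict[frozenset, int] = {}
        for members in member_sets.values():
            key = frozenset(members)
            out[key] = out.get(key, 0) + 1
        return out

    rxn_members: dict[tuple, set] = {}
    for m in models:
        for r in m.reactions:
            rxn_members.setdefault(_reaction_signature(r.stoichiometry), set()).add(m.id)
    met_members: dict[str, set] = {}
    for m in models:
        for met in m.metabolites:
            met_members.setdefault(_strip_compartment(met.id), set()).add(m.id)
    id_members: dict[str, set] = {}
    for m in models:
        for r in m.reactions:
            id_members.setdefault(r.id, set()).add(m.id)

    return ModelComparison(
        model_ids=ids,
        reaction_regions=regions(rxn_members),
        metabolite_regions=regions(met_members),
        id_match_reaction_regions=regions(id_members),
    )
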