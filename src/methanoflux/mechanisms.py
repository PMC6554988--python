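"""Methane-oxidation mechanism variants and the mechanism-discrimination panel.

Particulate methane monooxygenase (pMMO) oxidises CH4 to methanol using O2
and a two-electron donor whose identity is uncertain.  Three hypotheses are
modelled as alternative constraint sets on the same network:

* ``redox_arm`` — the donor is ubiquinol, regenerated from NADH by complex I;
  only the ubiquinol-coupled pMMO stoichiometry is open and complex III runs
  forward only.
* ``direct_coupling`` — the donor is cytochrome c, re-reduced by methanol
  dehydrogenase; only the cytochrome-c-coupled pMMO is open.
* ``uphill`` — ubiquinol is regenerated from cytochrome c by reverse
  (proton-motive-force-driven) flux through complex III; the
  ubiquinol-coupled pMMO is open and complex III may run backwards.

Because the electron donor determines how many translocated protons are
forgone per CH4 activated, the three variants predict different biomass
yields; comparing them with the measured yield discriminates the mechanism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields

from .model_core import MetabolicModel, DEFAULT_BOUND
from .lp_engine import fba, pfba, FluxSolution
from .synthetic_data import CORE_ID_MAP

__all__ = [
    "MechanismVariant",
    "ReactionIdMap",
    "VARIANT_NAMES",
    "mechanism_variant",
    "apply_mechanism",
    "mechanism_panel",
    "oxygen_methane_ratio",
]

VARIANT_NAMES = ("redox_arm", "direct_coupling", "uphill")


@dataclass(frozen=True)
class ReactionIdMap:
    """Maps canonical reaction roles to model-specific reaction ids.

    The same scenario code runs on the packaged core model or on an
    externally deposited model with different id spellings; load a JSON
    object with these keys via :meth:`from_json`.
    """

    pmmo_cytc: str = CORE_ID_MAP["pmmo_cytc"]
    pmmo_ubiquinol: str = CORE_ID_MAP["pmmo_ubiquinol"]
    complex_iii: str = CORE_ID_MAP["complex_iii"]
    atp_maintenance: str = CORE_ID_MAP["atp_maintenance"]
    biomass: str = CORE_ID_MAP["biomass"]
    phb_degradation: str = CORE_ID_MAP["phb_degradation"]
    glycine_synthase: str = CORE_ID_MAP["glycine_synthase"]
    malyl_coa_lyase: str = CORE_ID_MAP["malyl_coa_lyase"]
    methylmalyl_coa_lyase: str = CORE_ID_MAP["methylmalyl_coa_lyase"]
    propionyl_coa_carboxylase: str = CORE_ID_MAP["propionyl_coa_carboxylase"]
    ex_ch4: str = CORE_ID_MAP["ex_ch4"]
    ex_o2: str = CORE_ID_MAP["ex_o2"]
    ex_co2: str = CORE_ID_MAP["ex_co2"]
    ex_nh4: str = CORE_ID_MAP["ex_nh4"]
    ex_no3: str = CORE_ID_MAP["ex_no3"]
    ex_acetate: str = CORE_ID_MAP["ex_acetate"]
    ex_butanediol: str = CORE_ID_MAP["ex_butanediol"]
    ex_phb: str = CORE_ID_MAP["ex_phb"]
    ex_biomass: str = CORE_ID_MAP["ex_biomass"]

    @classmethod
    def from_json(cls, path: str) -> "ReactionIdMap":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown id-map keys: {sorted(unknown)}")
        return cls(**data)


@dataclass(frozen=True)
class MechanismVariant:
    """Bound overrides realising one methane-oxidation hypothesis."""

    name: str
    active_reactions: frozenset[str]
    disabled_reactions: frozenset[str]
    reversibility_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)


def mechanism_variant(name: str, idmap: ReactionIdMap | None = None) -> MechanismVariant:
    """Build the named variant's constraint set for a given id map."""
    idmap = idmap or ReactionIdMap()
    fwd = (0.0, DEFAULT_BOUND)
    rev = (-DEFAULT_BOUND, DEFAULT_BOUND)
    if name == "redox_arm":
        return MechanismVariant(
            name=name,
            active_reactions=frozenset({idmap.pmmo_ubiquinol}),
            disabled_reactions=frozenset({idmap.pmmo_cytc}),
            reversibility_overrides={idmap.pmmo_ubiquinol: fwd,
                                     idmap.complex_iii: fwd},
        )
    if name == "direct_coupling":
        return MechanismVariant(
            name=name,
            active_reactions=frozenset({idmap.pmmo_cytc}),
            disabled_reactions=frozenset({idmap.pmmo_ubiquinol}),
            reversibility_overrides={idmap.pmmo_cytc: fwd,
                                     idmap.complex_iii: fwd},
        )
    if name == "uphill":
        # ubiquinol-coupled pMMO with complex III free to run backwards:
        # cytochrome-c electrons are pushed "uphill" onto ubiquinone at the
        # cost of the proton-motive force
        return MechanismVariant(
            name=name,
            active_reactions=frozenset({idmap.pmmo_ubiquinol}),
            disabled_reactions=frozenset({idmap.pmmo_cytc}),
            reversibility_overrides={idmap.pmmo_ubiquinol: fwd,
                                     idmap.complex_iii: rev},
        )
    raise ValueError(f"unknown mechanism variant {name!r}; expected one of {VARIANT_NAMES}")


def apply_mechanism(model: MetabolicModel, variant: MechanismVariant) -> MetabolicModel:
    """Return a copy of *model* with the variant's bounds applied.

    The inactive pMMO gets (0, 0) bounds; the original model is unmodified.
    Applying the same variant twice is idempotent.
    """
    needed = set(variant.active_reactions) | set(variant.disabled_reactions) \
        | set(variant.reversibility_overrides)
    missing = [r for r in needed if not model.has_reaction(r)]
    if missing:
        raise KeyError(
            f"model {model.id!r} lacks reaction(s) required by variant "
            f"{variant.name!r}: {missing}"
        )
    out = model.copy()
    for rid in variant.disabled_reactions:
        out.set_bounds(rid, 0.0, 0.0)
    for rid, (lb, ub) in variant.reversibility_overrides.items():
        out.set_bounds(rid, lb, ub)
    return out


def _growth_constraints(idmap: ReactionIdMap, uptake_ch4: float, ngam_atp: float):
    return {
        idmap.ex_ch4: (-uptake_ch4, -uptake_ch4),
        idmap.atp_maintenance: (ngam_atp, ngam_atp),
    }


def mechanism_panel(
    model: MetabolicModel,
    uptake_ch4: float,
    ngam_atp: float,
    idmap: ReactionIdMap | None = None,
) -> dict[str, dict]:
    """Predicted biomass yields on methane under all three mechanisms.

    For each variant: methane uptake is fixed at ``uptake_ch4`` (mmol
    g-DW^-1 h^-1), the maintenance flux is fixed at ``ngam_atp``, biomass is
    maximised, and the growth rate is converted to a yield via
    ``yield = 1000 * mu / uptake_ch4`` (g-DW per mol CH4).  Infeasible
    variants report a yield of 0 with ``feasible=False``.
    """
    if uptake_ch4 <= 0:
        raise ValueError("uptake_ch4 must be positive")
    if ngam_atp < 0:
        raise ValueError("ngam_atp must be non-negative")
    idmap = idmap or ReactionIdMap()
    eb = _growth_constraints(idmap, uptake_ch4, ngam_atp)
    panel: dict[str, dict] = {}
    for name in VARIANT_NAMES:
        variant = mechanism_variant(name, idmap)
        m = apply_mechanism(model, variant)
        sol = fba(m, idmap.biomass, "maximize", eb)
        if sol.ok:
            mu = sol.objective_value
            panel[name] = {
                "growth_rate": mu,
                "yield_gdw_per_mol": 1000.0 * mu / uptake_ch4,
                "o2_per_ch4": abs(sol.flux(idmap.ex_o2)) / uptake_ch4,
                "feasible": True,
            }
        else:
            panel[name] = {
                "growth_rate": 0.0,
                "yield_gdw_per_mol": 0.0,
                "o2_per_ch4": float("nan"),
                "feasible": False,
            }
    return panel


def oxygen_methane_ratio(
    model: MetabolicModel,
    uptake_ch4: float,
    ngam_atp: float,
    idmap: ReactionIdMap | None = None,
) -> float:
    """Molar O2/CH4 consumption ratio at the biomass optimum.

    The model is expected to already carry a mechanism variant (see
    :func:`apply_mechanism`); the ratio is read from the parsimonious
    optimum so the reported exchange fluxes are well determined.
    """
    if uptake_ch4 <= 0:
        raise ValueError("uptake_ch4 must be positive (zero methane flux)")
    idmap = idmap or ReactionIdMap()
    eb = _growth_constraints(idmap, uptake_ch4, ngam_atp)
    sol: FluxSolution = pfba(model, idmap.biomass, "maximize", eb)
    if not sol.ok:
        raise RuntimeError(f"biomass optimisation failed: status {sol.status}")
    ch4 = abs(sol.flux(idmap.ex_ch4))
    if ch4 <= 0:
        raise RuntimeError("zero methane flux at optimum")
    return abs(sol.flux(idmap.ex_o2)) / ch4
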