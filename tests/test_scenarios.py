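import math

import numpy as np
import pytest

from methanoflux import constants
from methanoflux.lp_engine import fva
from methanoflux.mechanisms import mechanism_variant
from methanoflux.model_core import MetabolicModel, Metabolite, Reaction
from methanoflux.scenarios import (
    BottleExperiment,
    anaplerosis_comparison,
    anoxic_overflow_pareto,
    anoxic_phb_atp,
    co_consumption,
    compare_models,
    degree_distribution,
    growth_rate_from_doubling_time,
    maintenance_from_endogenous_respiration,
    phb_amount_from_concentrations,
)
from methanoflux.synthetic_data import build_core_model, biomass_carbon_content


class TestDeskArithmetic:
    def test_doubling_time_to_growth_rate(self):
        assert growth_rate_from_doubling_time(6.45) == pytest.approx(0.107, abs=5e-4)
        assert growth_rate_from_doubling_time(math.log(2)) == pytest.approx(1.0)
        # ln2/4.94 is 0.140, not the 0.154 printed next to this doubling time
        assert growth_rate_from_doubling_time(4.94) == pytest.approx(0.140, abs=5e-4)
        with pytest.raises(ValueError):
            growth_rate_from_doubling_time(0.0)

    def test_maintenance_from_endogenous_respiration(self):
        ngam = maintenance_from_endogenous_respiration(0.71, 5.0)
        assert ngam == pytest.approx(3.55)
        assert float(f"{ngam:.2g}") == 3.5  # two significant figures as reported
        assert maintenance_from_endogenous_respiration(0.0, 5.0) == 0.0
        assert maintenance_from_endogenous_respiration(1.0, 5.0) == 5.0

    def test_phb_amount_from_concentrations(self):
        mmol = phb_amount_from_concentrations(0.16, 0.017, 0.050)
        assert mmol == pytest.approx(0.083, abs=5e-4)
        assert phb_amount_from_concentrations(0.3, 0.3, 1.0) == 0.0
        with pytest.raises(ValueError):
            phb_amount_from_concentrations(0.1, 0.2, 0.05)

    def test_monomer_mass_is_hydroxybutyrate_minus_water(self):
        # C4H8O3 = 104.10 g/mol, H2O = 18.02 g/mol
        assert constants.PHB_MONOMER_MASS == pytest.approx(104.10 - 18.02, abs=0.02)


@pytest.fixture(scope="module")
def bottle():
    return BottleExperiment(ch4_consumed=1.8, phb_consumed=0.083)


@pytest.fixture(scope="module")
def result(core_model, bottle):
    return co_consumption(core_model, bottle, mechanism_variant("redox_arm"))


class TestCoConsumption:
    def test_oxygen_prediction_matches_bottle_measurement(self, result):
        # measured 2.6 +/- 0.13 mmol O2 per bottle; redox-arm stoichiometry
        # pins the prediction at 1.5 x 1.8 = 2.7
        assert result.o2_mmol == pytest.approx(2.7, abs=0.05)

    def test_biomass_prediction_in_measured_range(self, result):
        # measured 21 +/- 3 mg of non-PHB dry biomass per bottle
        assert 15.0 <= result.biomass_mg <= 24.0

    def test_zero_inputs_give_zero_outputs(self, core_model):
        res = co_consumption(core_model, BottleExperiment(ch4_consumed=0.0,
                                                          phb_consumed=0.0),
                             mechanism_variant("redox_arm"))
        assert res.biomass_mg == pytest.approx(0.0, abs=1e-6)
        assert res.o2_mmol == pytest.approx(0.0, abs=1e-6)

    def test_linearity_doubling_inputs_doubles_outputs(self, core_model, result):
        doubled = co_consumption(
            core_model, BottleExperiment(ch4_consumed=3.6, phb_consumed=0.166),
            mechanism_variant("redox_arm"))
        assert doubled.biomass_mg == pytest.approx(2 * result.biomass_mg, rel=1e-5)
        assert doubled.o2_mmol == pytest.approx(2 * result.o2_mmol, rel=1e-5)

    def test_missing_phb_route_reported(self, core_model, bottle):
        broken = core_model.copy()
        broken.reactions = [r for r in broken.reactions if r.id != "PHBDEG"]
        broken = MetabolicModel(id="x", metabolites=broken.metabolites,
                                reactions=broken.reactions)
        with pytest.raises(KeyError, match="PHBDEG"):
            co_consumption(broken, bottle, None)

    def test_carbon_conservation_at_optimum(self, core_model, result):
        carbon_in = 1.8 * 1 + 0.083 * 4  # CH4 + PHB monomer (C4)
        sol_fluxes = result.fluxes
        biomass_c = biomass_carbon_content(core_model) * sol_fluxes["BIOMASS"]
        co2_out = sol_fluxes["EX_co2_e0"] * 1
        secreted = sol_fluxes["EX_ac_e0"] * 2 + sol_fluxes["EX_btd_e0"] * 4
        assert carbon_in == pytest.approx(biomass_c + co2_out + secreted, abs=1e-6)


@pytest.fixture(scope="module")
def comparison(core_model):
    return anaplerosis_comparison(core_model, mechanism_variant("redox_arm"))


class TestAnaplerosisPattern:
    def test_glycine_synthase_displaced_by_phb(self, comparison):
        ref, cc = comparison["methane_only"], comparison["co_consumption"]
        assert cc["glycine_synthase"] < ref["glycine_synthase"]
        per_ch4_ref = ref["glycine_synthase"] / ref["ch4_uptake"]
        per_ch4_cc = cc["glycine_synthase"] / cc["ch4_uptake"]
        assert per_ch4_cc < per_ch4_ref

    def test_phb_degradation_rises_from_zero(self, comparison):
        assert comparison["methane_only"]["phb_degradation"] == pytest.approx(0, abs=1e-9)
        assert comparison["co_consumption"]["phb_degradation"] == pytest.approx(0.608)

    def test_methylmalyl_lysis_equals_phb_degradation_rate(self, comparison):
        cc = comparison["co_consumption"]
        assert cc["methylmalyl_coa_lyase"] == pytest.approx(cc["phb_degradation"],
                                                           abs=1e-6)
        assert comparison["methane_only"]["methylmalyl_coa_lyase"] == pytest.approx(
            0.0, abs=1e-6)

    def test_propionyl_coa_carboxylation_accompanies_phb_use(self, comparison):
        assert comparison["co_consumption"]["propionyl_coa_carboxylase"] > 0.5
        assert comparison["methane_only"]["propionyl_coa_carboxylase"] == pytest.approx(
            0.0, abs=1e-6)

    def test_growth_rate_rises_under_co_consumption(self, comparison):
        assert comparison["co_consumption"]["growth_rate"] > \
            comparison["methane_only"]["growth_rate"]


class TestAnoxicPhb:
    def test_no_atp_without_nitrate(self, core_model):
        atp, feasible = anoxic_phb_atp(core_model, allow_nitrate=False)
        assert atp == 0.0
        assert not feasible

    def test_atp_coupled_to_denitrification(self, core_model):
        atp, feasible = anoxic_phb_atp(core_model, allow_nitrate=True)
        assert feasible
        assert atp > 1.0

    def test_no_atp_when_denitrification_chain_blocked(self):
        model = build_core_model()
        for rid in ("NAR", "NIR", "NOR", "NOS"):
            model.set_bounds(rid, 0.0, 0.0)
        atp, feasible = anoxic_phb_atp(model, allow_nitrate=True)
        assert atp == 0.0 and not feasible

    def test_no_denitrification_build_cannot_make_anoxic_atp(self):
        from methanoflux.synthetic_data import CoreModelSpec
        model = build_core_model(CoreModelSpec(include_denitrification=False))
        # nitrate exchange is absent entirely: fall back to blocking oxygen only
        from methanoflux.lp_engine import fba
        sol = fba(model, "ATPM", "maximize", {
            "EX_o2_e0": (0.0, 0.0), "EX_ch4_e0": (0.0, 0.0),
            "EX_phb_c0": (-1.0, 0.0), "PHBDEG": (1.0, 1.0),
            "ATPM": (0.0, 1000.0),
        })
        assert (not sol.ok) or sol.objective_value <= 1e-9


@pytest.fixture(scope="module", params=["acetate", "butanediol"])
def curve(core_model, request):
    return anoxic_overflow_pareto(core_model, request.param, n_points=9)


class TestOverflowPareto:
    def test_max_atp_at_zero_product(self, curve):
        feas = [p for p in curve if p.feasible]
        assert feas[0].forced_product == 0.0
        assert all(feas[0].max_objective >= p.max_objective - 1e-9 for p in feas)

    def test_atp_non_increasing_along_grid(self, curve):
        vals = [p.max_objective for p in curve if p.feasible]
        assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))

    def test_less_nitrate_needed_for_product_than_for_atp(self, curve):
        feas = [p for p in curve if p.feasible]
        assert feas[-1].acceptor_consumed < feas[0].acceptor_consumed - 1e-6

    def test_all_grid_points_reported(self, curve):
        assert len(curve) == 9


class TestDegreeDistribution:
    def test_counts_sum_to_connected_metabolites(self, core_model):
        dist = degree_distribution(core_model)
        n_connected = len({m for r in core_model.reactions for m in r.stoichiometry})
        assert dist.n_connected + len(dist.excluded_hubs) == n_connected

    def test_hubs_are_cofactors(self, core_model):
        dist = degree_distribution(core_model)
        assert dist.excluded_hubs  # ATP/NADH-type metabolites exceed the power law
        assert set(dist.excluded_hubs) & {"atp_c0", "nadh_c0", "h2o_c0", "h_c0"}

    def test_uniform_degree_model_flagged_single_point(self):
        mets = [Metabolite(id=f"M{i}_c0") for i in range(4)]
        rxns = [
            Reaction(id=f"r{i}", stoichiometry={f"M{i}_c0": -1.0,
                                                f"M{(i + 1) % 4}_c0": 1.0},
                     lower_bound=0, upper_bound=1)
            for i in range(4)
        ]
        m = MetabolicModel(id="ring", metabolites=mets, reactions=rxns)
        dist = degree_distribution(m)
        assert dist.single_point
        assert math.isnan(dist.fitted_slope)
        assert dist.counts == {2: 4}

    def test_slope_invariant_to_log_base(self, core_model):
        dist = degree_distribution(core_model)
        ks = np.array(sorted(dist.counts), dtype=float)
        ns = np.array([dist.counts[int(k)] for k in ks], dtype=float)
        slope_ln, _ = np.polyfit(np.log(ks), np.log(ns), 1)
        assert slope_ln == pytest.approx(dist.fitted_slope, rel=1e-9)

    def test_active_only_uses_smaller_network(self, core_model, methane_growth_bounds):
        res = fva(core_model, "BIOMASS", fraction=1.0,
                  extra_bounds=methane_growth_bounds)
        active = degree_distribution(core_model, active_only=True, fva_result=res)
        full = degree_distribution(core_model)
        assert active.n_connected < full.n_connected


class TestCompareModels:
    def test_model_compared_with_itself_has_no_unique(self, core_model):
        other = core_model.copy()
        other.id = "clone"
        cmp = compare_models([core_model, other])
        assert cmp.unique_reactions("methanotroph_core") == 0
        assert cmp.unique_reactions("clone") == 0
        # everything shared; count equals the number of distinct signatures
        assert cmp.shared_reactions() == sum(cmp.reaction_regions.values())
        assert cmp.shared_reactions() <= len(core_model.reactions)

    def test_single_added_reaction_detected(self, core_model):
        other = core_model.copy()
        other.id = "plus_one"
        other.add_metabolite(Metabolite(id="ade_c0", formula="C5H5N5"))
        other.add_reaction(Reaction(
            id="PNP", stoichiometry={"ade_c0": -1.0, "pi_c0": -1.0, "gly_c0": 1.0},
            lower_bound=0, upper_bound=10))
        cmp = compare_models([core_model, other])
        assert cmp.unique_reactions("plus_one") == 1
        assert cmp.unique_reactions("methanotroph_core") == 0

    def test_signature_matching_ignores_id_spelling(self, core_model):
        renamed = core_model.copy()
        renamed.id = "respelled"
        # respell one reaction id: signature matching must still pair it
        r = renamed.reaction("GLYS")
        renamed.reactions = [x for x in renamed.reactions if x.id != "GLYS"]
        r = Reaction(id="rxn99999_c0", stoichiometry=r.stoichiometry,
                     lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        renamed.reactions.append(r)
        renamed = MetabolicModel(id="respelled", metabolites=renamed.metabolites,
                                 reactions=renamed.reactions)
        cmp = compare_models([core_model, renamed])
        assert cmp.unique_reactions("respelled") == 0
        # while plain id matching would miscount
        assert cmp.id_match_reaction_regions[frozenset({"respelled"})] == 1

    def test_fewer_than_two_models_rejected(self, core_model):
        with pytest.raises(ValueError):
            compare_models([core_model])

    def test_region_counts_sum_to_union(self, core_model):
        other = core_model.copy()
        other.id = "clone"
        cmp = compare_models([core_model, other])
        assert sum(cmp.reaction_regions.values()) == cmp.shared_reactions()
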