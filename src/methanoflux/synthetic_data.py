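"""Core methanotroph fixture model and random-network generators.

:func:`build_core_model` assembles a compact (~70 reaction) type II
methanotroph network containing every pathway the scenario analyses
traverse: both candidate pMMO stoichiometries, methanol/formaldehyde/formate
oxidation, formaldehyde entry into the C1 (tetrahydrofolate) pool, the full
serine cycle with a malyl-CoA lyase shared between malyl-CoA and
l-erythro-3-methylmalyl-CoA cleavage, glycine synthase, PHB synthesis and an
ethylmalonyl-CoA-type degradation route ending in glyoxylate +
propionyl-CoA, propionyl-CoA carboxylation to succinyl-CoA, the TCA cycle, a
respiratory chain with explicit proton translocation calibrated to 5 ATP per
O2, a four-step denitrification chain, acetate and butane-2,3-diol overflow
routes, and a biomass reaction.

Every non-exchange, non-biomass reaction is elementally balanced for
C/H/O/N/P/S under the module's carrier conventions (reduced carriers carry
their electrons as H in the formula; the translocated proton is a distinct
periplasmic species so proton-motive force cannot short-circuit).

:func:`random_network` provides reproducible random stoichiometric networks:
a mass-consistent "pathway" mode used to cross-check the LP engine against a
brute-force oracle, and a "scale_free" mode that samples metabolite degrees
from P(k) proportional to k^-gamma for degree-distribution recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model_core import (
    MetabolicModel,
    Metabolite,
    Reaction,
    parse_equation,
)
from . import constants

__all__ = [
    "CoreModelSpec",
    "build_core_model",
    "random_network",
    "CORE_ID_MAP",
    "BIOMASS_TEMPLATE",
    "DEFAULT_CARBON_SCALE",
    "DEFAULT_GAM_ATP",
]

# ---------------------------------------------------------------------------
# Biomass calibration constants
# ---------------------------------------------------------------------------
# The biomass reaction drains serine-cycle and TCA precursors plus
# growth-associated ATP.  The relative precursor proportions below are fixed
# a priori (roughly protein-dominated biomass: C2/C3/C4/C5 skeletons plus
# ammonium and biosynthetic reducing power); the overall carbon scale and the
# growth-associated ATP were tuned once, by scripts/calibrate_biomass.py, so
# that redox-arm growth at methane uptake 14.9 and NGAM 3.5 reproduces the
# measured mu = 0.107 h^-1 and O2/CH4 = 1.5.  They are artifact constants of
# this fixture, not literature values.

#: mmol precursor per g DW at carbon_scale = 1 (before scaling).
BIOMASS_TEMPLATE = {
    "accoa": 3.0,   # lipids, leucine/lysine families
    "ser": 1.5,     # serine/glycine/cysteine families + C1 units
    "akg": 1.1,     # glutamate family
    "oaa": 1.8,     # aspartate family, pyrimidines
    "nh4": 6.0,     # nitrogen beyond the serine skeleton
    "nadh": 1.4,    # net biosynthetic reducing power
}

#: Calibrated multiplier on the carbon precursors (see calibrate_biomass.py).
DEFAULT_CARBON_SCALE = 3.598252

#: Growth-associated maintenance, mmol ATP per g DW.
DEFAULT_GAM_ATP = 40.0


@dataclass
class CoreModelSpec:
    """Build options for the core fixture model."""

    include_denitrification: bool = True
    include_overflow_products: bool = True
    atp_per_o2_target: float = 5.0
    biomass_calibration: dict[str, float] = field(
        default_factory=lambda: {
            "carbon_scale": DEFAULT_CARBON_SCALE,
            "gam_atp": DEFAULT_GAM_ATP,
        }
    )


#: Canonical reaction-id map of the fixture (see mechanisms.ReactionIdMap).
CORE_ID_MAP = {
    "pmmo_cytc": "pMMO1",
    "pmmo_ubiquinol": "pMMO2",
    "complex_iii": "CPLX3",
    "atp_maintenance": "ATPM",
    "biomass": "BIOMASS",
    "phb_degradation": "PHBDEG",
    "glycine_synthase": "GLYS",
    "malyl_coa_lyase": "MCL1",
    "methylmalyl_coa_lyase": "MCL2",
    "propionyl_coa_carboxylase": "PCC",
    "ex_ch4": "EX_ch4_e0",
    "ex_o2": "EX_o2_e0",
    "ex_co2": "EX_co2_e0",
    "ex_nh4": "EX_nh4_e0",
    "ex_no3": "EX_no3_e0",
    "ex_acetate": "EX_ac_e0",
    "ex_butanediol": "EX_btd_e0",
    "ex_phb": "EX_phb_c0",
    "ex_biomass": "EX_biomass_c0",
}


# (id, name, formula) triplets; compartment parsed from the id suffix.
_METABOLITES: list[tuple[str, str, str]] = [
    # extracellular
    ("ch4_e0", "methane (ext)", "CH4"),
    ("o2_e0", "oxygen (ext)", "O2"),
    ("co2_e0", "carbon dioxide (ext)", "CO2"),
    ("nh4_e0", "ammonium (ext)", "H4N"),
    ("no3_e0", "nitrate (ext)", "NO3"),
    ("n2_e0", "dinitrogen (ext)", "N2"),
    ("ac_e0", "acetate (ext)", "C2H4O2"),
    ("btd_e0", "butane-2,3-diol (ext)", "C4H10O2"),
    ("h2o_e0", "water (ext)", "H2O"),
    # periplasmic translocated proton (proton-motive force carrier)
    ("hpm_p0", "translocated proton", "H"),
    # cytosolic small molecules
    ("ch4_c0", "methane", "CH4"),
    ("o2_c0", "oxygen", "O2"),
    ("co2_c0", "carbon dioxide", "CO2"),
    ("h2o_c0", "water", "H2O"),
    ("h_c0", "proton", "H"),
    ("nh4_c0", "ammonium", "H4N"),
    ("no3_c0", "nitrate", "NO3"),
    ("no2_c0", "nitrite", "NO2"),
    ("no_c0", "nitric oxide", "NO"),
    ("n2o_c0", "nitrous oxide", "N2O"),
    ("n2_c0", "dinitrogen", "N2"),
    ("meoh_c0", "methanol", "CH4O"),
    ("fald_c0", "formaldehyde", "CH2O"),
    ("for_c0", "formate", "CH2O2"),
    ("thf_c0", "tetrahydrofolate", "C19H23N7O6"),
    ("mlthf_c0", "5,10-methylene-THF", "C20H23N7O6"),
    # redox and energy carriers (reduced forms carry electrons as H)
    ("nad_c0", "NAD+", "C21H26N7O14P2"),
    ("nadh_c0", "NADH", "C21H27N7O14P2"),
    ("q8_c0", "ubiquinone-8", "C49H74O4"),
    ("q8h2_c0", "ubiquinol-8", "C49H76O4"),
    ("cytcox_c0", "cytochrome c (oxidised)", "C42H44FeN8O8S2"),
    ("cytcred_c0", "cytochrome c (reduced)", "C42H45FeN8O8S2"),
    ("atp_c0", "ATP", "C10H16N5O13P3"),
    ("adp_c0", "ADP", "C10H15N5O10P2"),
    ("pi_c0", "phosphate", "H3O4P"),
    # CoA thioesters
    ("coa_c0", "coenzyme A", "C21H36N7O16P3S"),
    ("accoa_c0", "acetyl-CoA", "C23H38N7O17P3S"),
    ("aacoa_c0", "acetoacetyl-CoA", "C25H40N7O18P3S"),
    ("hbcoa_c0", "(R)-3-hydroxybutyryl-CoA", "C25H42N7O18P3S"),
    ("mmalcoa_c0", "l-erythro-3-methylmalyl-CoA", "C26H42N7O20P3S"),
    ("malylcoa_c0", "malyl-CoA", "C25H40N7O20P3S"),
    ("ppcoa_c0", "propionyl-CoA", "C24H40N7O17P3S"),
    ("succoa_c0", "succinyl-CoA", "C25H40N7O19P3S"),
    # central carbon
    ("glx_c0", "glyoxylate", "C2H2O3"),
    ("gly_c0", "glycine", "C2H5NO2"),
    ("ser_c0", "serine", "C3H7NO3"),
    ("hpyr_c0", "hydroxypyruvate", "C3H4O4"),
    ("glyc_c0", "glycerate", "C3H6O4"),
    ("pep_c0", "phosphoenolpyruvate", "C3H5O6P"),
    ("pyr_c0", "pyruvate", "C3H4O3"),
    ("oaa_c0", "oxaloacetate", "C4H4O5"),
    ("mal_c0", "malate", "C4H6O5"),
    ("fum_c0", "fumarate", "C4H4O4"),
    ("succ_c0", "succinate", "C4H6O4"),
    ("cit_c0", "citrate", "C6H8O7"),
    ("icit_c0", "isocitrate", "C6H8O7"),
    ("akg_c0", "alpha-ketoglutarate", "C5H6O5"),
    ("tsa_c0", "tartronate semialdehyde", "C3H4O4"),
    ("ala_c0", "alanine", "C3H7NO2"),
    ("bhb_c0", "(R)-3-hydroxybutyrate", "C4H8O3"),
    ("acac_c0", "acetoacetate", "C4H6O3"),
    # storage and overflow
    ("phb_c0", "PHB (monomer equivalent)", "C4H6O2"),
    ("alac_c0", "acetolactate", "C5H8O4"),
    ("actn_c0", "acetoin", "C4H8O2"),
    ("btd_c0", "butane-2,3-diol", "C4H10O2"),
    ("ac_c0", "acetate", "C2H4O2"),
]

_B = 1000.0  # default wide bound

# (id, name, equation, lb, ub); equations use model_core's equation grammar.
_REACTIONS: list[tuple[str, str, str, float, float]] = [
    # exchanges (secretion positive; uptake = negative lower bound)
    ("EX_ch4_e0", "methane exchange", "ch4_e0 ->", -_B, _B),
    ("EX_o2_e0", "oxygen exchange", "o2_e0 ->", -_B, _B),
    ("EX_co2_e0", "CO2 exchange", "co2_e0 ->", -_B, _B),
    ("EX_nh4_e0", "ammonium exchange", "nh4_e0 ->", -_B, _B),
    ("EX_no3_e0", "nitrate exchange", "no3_e0 ->", 0.0, 0.0),
    ("EX_n2_e0", "dinitrogen exchange", "n2_e0 ->", 0.0, _B),
    ("EX_ac_e0", "acetate exchange", "ac_e0 ->", 0.0, _B),
    ("EX_btd_e0", "butane-2,3-diol exchange", "btd_e0 ->", 0.0, _B),
    ("EX_h2o_e0", "water exchange", "h2o_e0 ->", -_B, _B),
    ("EX_h_c0", "proton sink/source", "h_c0 ->", -_B, _B),
    ("EX_phb_c0", "PHB granule storage boundary", "phb_c0 ->", 0.0, _B),
    ("EX_biomass_c0", "biomass sink", "biomass_c0 ->", 0.0, _B),
    # transport (passive, reversible)
    ("T_ch4", "methane diffusion", "ch4_e0 <=> ch4_c0", -_B, _B),
    ("T_o2", "oxygen diffusion", "o2_e0 <=> o2_c0", -_B, _B),
    ("T_co2", "CO2 diffusion", "co2_e0 <=> co2_c0", -_B, _B),
    ("T_nh4", "ammonium transport", "nh4_e0 <=> nh4_c0", -_B, _B),
    ("T_no3", "nitrate transport", "no3_e0 <=> no3_c0", -_B, _B),
    ("T_n2", "dinitrogen diffusion", "n2_c0 <=> n2_e0", -_B, _B),
    ("T_ac", "acetate transport", "ac_c0 <=> ac_e0", -_B, _B),
    ("T_btd", "butane-2,3-diol transport", "btd_c0 <=> btd_e0", -_B, _B),
    ("T_h2o", "water diffusion", "h2o_e0 <=> h2o_c0", -_B, _B),
    # methane oxidation: two alternative pMMO electron-donor stoichiometries
    ("pMMO1", "pMMO (cytochrome-c coupled)",
     "ch4_c0 + o2_c0 + 2 cytcred_c0 -> meoh_c0 + h2o_c0 + 2 cytcox_c0", 0.0, _B),
    ("pMMO2", "pMMO (ubiquinol coupled)",
     "ch4_c0 + o2_c0 + q8h2_c0 -> meoh_c0 + h2o_c0 + q8_c0", 0.0, _B),
    ("MEDH", "methanol dehydrogenase (cytochrome c)",
     "meoh_c0 + 2 cytcox_c0 -> fald_c0 + 2 cytcred_c0", 0.0, _B),
    ("FALDH", "formaldehyde dehydrogenase",
     "fald_c0 + h2o_c0 + nad_c0 -> for_c0 + nadh_c0 + h_c0", 0.0, _B),
    ("FDH", "formate dehydrogenase",
     "for_c0 + nad_c0 -> co2_c0 + nadh_c0 + h_c0", 0.0, _B),
    ("FAE", "formaldehyde-THF condensation",
     "fald_c0 + thf_c0 -> mlthf_c0 + h2o_c0", 0.0, _B),
    # serine cycle
    ("SHMT", "serine hydroxymethyltransferase",
     "gly_c0 + mlthf_c0 + h2o_c0 -> ser_c0 + thf_c0", 0.0, _B),
    ("SGA", "serine-glyoxylate aminotransferase",
     "ser_c0 + glx_c0 -> hpyr_c0 + gly_c0", 0.0, _B),
    ("HPR", "hydroxypyruvate reductase",
     "hpyr_c0 + nadh_c0 + h_c0 -> glyc_c0 + nad_c0", 0.0, _B),
    ("GCK", "glycerate kinase + enolase (lumped)",
     "glyc_c0 + atp_c0 -> pep_c0 + adp_c0 + h2o_c0", 0.0, _B),
    ("PPC", "PEP carboxylase",
     "pep_c0 + co2_c0 + h2o_c0 -> oaa_c0 + pi_c0", 0.0, _B),
    ("MDH", "malate dehydrogenase",
     "oaa_c0 + nadh_c0 + h_c0 <=> mal_c0 + nad_c0", -_B, _B),
    ("MTK", "malate thiokinase",
     "mal_c0 + coa_c0 + atp_c0 <=> malylcoa_c0 + adp_c0 + pi_c0", -_B, _B),
    ("MCL1", "malyl-CoA lyase (malyl-CoA cleavage)",
     "malylcoa_c0 <=> glx_c0 + accoa_c0", -_B, _B),
    ("GLYS", "glycine synthase (reverse cleavage system)",
     "co2_c0 + mlthf_c0 + nh4_c0 + nadh_c0 -> gly_c0 + thf_c0 + nad_c0", 0.0, _B),
    ("GCL", "glyoxylate carboligase",
     "2 glx_c0 -> tsa_c0 + co2_c0", 0.0, _B),
    ("TSR", "tartronate semialdehyde reductase",
     "tsa_c0 + nadh_c0 + h_c0 -> glyc_c0 + nad_c0", 0.0, _B),
    # deaminating shuttle: net serine -> hydroxypyruvate without consuming
    # glyoxylate, so glycine synthase can also cover C3/C4 withdrawal
    ("SPT", "serine-pyruvate aminotransferase",
     "ser_c0 + pyr_c0 -> hpyr_c0 + ala_c0", 0.0, _B),
    ("ALD", "alanine dehydrogenase",
     "ala_c0 + h2o_c0 + nad_c0 -> pyr_c0 + nh4_c0 + nadh_c0", 0.0, _B),
    # TCA cycle
    ("CS", "citrate synthase",
     "accoa_c0 + oaa_c0 + h2o_c0 -> cit_c0 + coa_c0", 0.0, _B),
    ("ACO", "aconitase", "cit_c0 <=> icit_c0", -_B, _B),
    ("ICD", "isocitrate dehydrogenase",
     "icit_c0 + nad_c0 -> akg_c0 + co2_c0 + nadh_c0 + h_c0", 0.0, _B),
    ("AKGDH", "alpha-ketoglutarate dehydrogenase",
     "akg_c0 + coa_c0 + nad_c0 -> succoa_c0 + co2_c0 + nadh_c0 + h_c0", 0.0, _B),
    ("SCS", "succinyl-CoA synthetase",
     "succoa_c0 + adp_c0 + pi_c0 <=> succ_c0 + coa_c0 + atp_c0", -_B, _B),
    ("SDH", "succinate dehydrogenase",
     "succ_c0 + q8_c0 -> fum_c0 + q8h2_c0", 0.0, _B),
    ("FUM", "fumarase", "fum_c0 + h2o_c0 <=> mal_c0", -_B, _B),
    # respiratory chain (10 H+ per NADH across complexes I+III+IV)
    ("CPLX1", "NADH dehydrogenase (complex I)",
     "nadh_c0 + q8_c0 + 5 h_c0 -> nad_c0 + q8h2_c0 + 4 hpm_p0", 0.0, _B),
    ("CPLX3", "cytochrome bc1 (complex III)",
     "q8h2_c0 + 2 cytcox_c0 + 2 h_c0 -> q8_c0 + 2 cytcred_c0 + 2 hpm_p0", 0.0, _B),
    ("CPLX4", "cytochrome c oxidase (complex IV)",
     "2 cytcred_c0 + 0.5 o2_c0 + 4 h_c0 -> 2 cytcox_c0 + h2o_c0 + 4 hpm_p0",
     0.0, _B),
    # ATP synthase stoichiometry is derived from CoreModelSpec.atp_per_o2_target
    # (placeholder row replaced in build_core_model)
    ("ATPS", "ATP synthase",
     "adp_c0 + pi_c0 + 4 hpm_p0 <=> atp_c0 + h2o_c0 + 4 h_c0", -_B, _B),
    ("ATPM", "ATP maintenance (non-growth)",
     "atp_c0 + h2o_c0 -> adp_c0 + pi_c0", 0.0, _B),
    # PHB synthesis and mobilisation
    ("PHAA", "beta-ketothiolase",
     "2 accoa_c0 <=> aacoa_c0 + coa_c0", -_B, _B),
    ("PHAB", "acetoacetyl-CoA reductase (synthesis-directed)",
     "aacoa_c0 + nadh_c0 + h_c0 -> hbcoa_c0 + nad_c0", 0.0, _B),
    ("PHAC", "PHB synthase", "hbcoa_c0 -> phb_c0 + coa_c0", 0.0, _B),
    ("PHBTE", "3-hydroxybutyryl-CoA thioesterase",
     "hbcoa_c0 + h2o_c0 -> bhb_c0 + coa_c0", 0.0, _B),
    ("BDH1", "3-hydroxybutyrate dehydrogenase",
     "bhb_c0 + nad_c0 -> acac_c0 + nadh_c0 + h_c0", 0.0, _B),
    ("SCOT", "succinyl-CoA:acetoacetate CoA-transferase",
     "acac_c0 + succoa_c0 -> aacoa_c0 + succ_c0", 0.0, _B),
    ("PHBDEG", "PHB depolymerase + 3HB-CoA ligation (lumped entry)",
     "phb_c0 + coa_c0 + atp_c0 + h2o_c0 -> hbcoa_c0 + adp_c0 + pi_c0", 0.0, _B),
    # ethylmalonyl-CoA-type degradation route; the interior steps
    # (crotonase, crotonyl-CoA carboxylase/reductase, ethylmalonyl-CoA
    # mutase, methylsuccinyl-CoA dehydrogenase, mesaconyl-CoA hydratase)
    # are lumped into one desk-scale reaction ending at methylmalyl-CoA
    ("EMCL", "ethylmalonyl-CoA pathway (lumped to l-erythro-3-methylmalyl-CoA)",
     "hbcoa_c0 + co2_c0 + nadh_c0 + h_c0 + q8_c0 -> mmalcoa_c0 + nad_c0 + q8h2_c0",
     0.0, _B),
    ("MCL2", "malyl-CoA lyase (methylmalyl-CoA cleavage)",
     "mmalcoa_c0 <=> glx_c0 + ppcoa_c0", -_B, _B),
    ("PCC", "propionyl-CoA carboxylase + mutase (lumped)",
     "ppcoa_c0 + co2_c0 + atp_c0 + h2o_c0 -> succoa_c0 + adp_c0 + pi_c0",
     0.0, _B),
    # anaplerotic/overflow branch points
    ("PYK", "pyruvate kinase", "pep_c0 + adp_c0 -> pyr_c0 + atp_c0", 0.0, _B),
    ("PEPCK", "PEP carboxykinase",
     "oaa_c0 + atp_c0 -> pep_c0 + co2_c0 + adp_c0", 0.0, _B),
    ("POXB", "pyruvate oxidase (quinone-linked)",
     "pyr_c0 + h2o_c0 + q8_c0 -> ac_c0 + co2_c0 + q8h2_c0", 0.0, _B),
    ("ALS", "acetolactate synthase", "2 pyr_c0 -> alac_c0 + co2_c0", 0.0, _B),
    ("ALDC", "acetolactate decarboxylase",
     "alac_c0 -> actn_c0 + co2_c0", 0.0, _B),
    ("BDH", "butanediol dehydrogenase",
     "actn_c0 + nadh_c0 + h_c0 -> btd_c0 + nad_c0", 0.0, _B),
    ("PTA_ACK", "phosphotransacetylase + acetate kinase (lumped)",
     "accoa_c0 + adp_c0 + pi_c0 -> ac_c0 + atp_c0 + coa_c0", 0.0, _B),
    # denitrification chain (nitrate -> dinitrogen)
    ("NAR", "nitrate reductase",
     "no3_c0 + q8h2_c0 -> no2_c0 + q8_c0 + h2o_c0", 0.0, _B),
    ("NIR", "nitrite reductase",
     "no2_c0 + cytcred_c0 + h_c0 -> no_c0 + cytcox_c0 + h2o_c0", 0.0, _B),
    ("NOR", "nitric oxide reductase",
     "2 no_c0 + 2 cytcred_c0 -> n2o_c0 + 2 cytcox_c0 + h2o_c0", 0.0, _B),
    ("NOS", "nitrous oxide reductase",
     "n2o_c0 + 2 cytcred_c0 -> n2_c0 + 2 cytcox_c0 + h2o_c0", 0.0, _B),
]

_DENITRIFICATION_IDS = {"NAR", "NIR", "NOR", "NOS", "T_no3", "EX_no3_e0",
                        "T_n2", "EX_n2_e0"}
_OVERFLOW_IDS = {"ALS", "ALDC", "BDH", "PTA_ACK", "T_ac", "T_btd",
                 "EX_ac_e0", "EX_btd_e0"}


def _biomass_reaction(spec: CoreModelSpec) -> tuple[dict[str, float], dict[str, int]]:
    """Biomass stoichiometry and the balancing elemental formula of biomass.

    Returns the signed stoichiometry (biomass flux of 1 = 1 g DW h^-1 per
    g DW, i.e. a specific growth rate of 1 h^-1) and the pseudo-formula
    assigned to the biomass metabolite so the reaction conserves C/H/O/N.
    """
    cal = spec.biomass_calibration
    chi = cal.get("carbon_scale", DEFAULT_CARBON_SCALE)
    gam = cal.get("gam_atp", DEFAULT_GAM_ATP)
    t = {k: cal.get(k, v) for k, v in BIOMASS_TEMPLATE.items()}

    # coefficients rounded to 9 decimals so they are decimal-representable
    # and survive SBML/TSV round trips bit-exactly
    stoich = {
        "accoa_c0": -round(t["accoa"] * chi, 9),
        "ser_c0": -round(t["ser"] * chi, 9),
        "akg_c0": -round(t["akg"] * chi, 9),
        "oaa_c0": -round(t["oaa"] * chi, 9),
        "nh4_c0": -round(t["nh4"] * chi, 9),
        "nadh_c0": -round(t["nadh"] * chi, 9),
        "atp_c0": -gam,
        "h2o_c0": -gam,
        "coa_c0": round(t["accoa"] * chi, 9),
        "nad_c0": round(t["nadh"] * chi, 9),
        "adp_c0": gam,
        "pi_c0": gam,
        "biomass_c0": 1.0,
    }
    # net element content drained into 1 unit of biomass (ATP+H2O->ADP+Pi
    # cancels elementally; acetyl-CoA minus CoA leaves C2H2O; NADH minus
    # NAD+ leaves H)
    a, d, b, c, e, f = (t["accoa"] * chi, t["ser"] * chi, t["akg"] * chi,
                        t["oaa"] * chi, t["nh4"] * chi, t["nadh"] * chi)
    formula_counts = {
        "C": 2 * a + 3 * d + 5 * b + 4 * c,
        "H": 2 * a + 7 * d + 6 * b + 4 * c + 4 * e + f,
        "O": a + 3 * d + 5 * b + 5 * c,
        "N": d + e,
    }
    return stoich, formula_counts


def build_core_model(spec: CoreModelSpec | None = None) -> MetabolicModel:
    """Assemble the core methanotroph fixture model.

    The returned model is validated, elementally balanced outside exchanges
    and biomass, and feasible for growth on methane at the reference
    constraints (uptake 14.9 mmol g-DW^-1 h^-1, NGAM 3.5) under any of the
    three methane-oxidation mechanism variants.
    """
    spec = spec or CoreModelSpec()

    mets = [Metabolite(id=i, name=n, formula=f) for i, n, f in _METABOLITES]
    model = MetabolicModel(id="methanotroph_core", metabolites=mets, reactions=[])

    for rid, name, eq, lb, ub in _REACTIONS:
        if not spec.include_denitrification and rid in _DENITRIFICATION_IDS:
            continue
        if not spec.include_overflow_products and rid in _OVERFLOW_IDS:
            continue
        if rid == "ATPS":
            # protons per ATP chosen so that full NADH oxidation (10 H+
            # translocated per NADH, 2 NADH per O2) yields the target ATP/O2
            h_per_atp = 20.0 / spec.atp_per_o2_target
            eq = (f"adp_c0 + pi_c0 + {h_per_atp} hpm_p0 <=> "
                  f"atp_c0 + h2o_c0 + {h_per_atp} h_c0")
        stoich, _ = parse_equation(eq)
        model.add_reaction(Reaction(
            id=rid, name=name, stoichiometry=stoich,
            lower_bound=lb, upper_bound=ub,
            is_exchange=len(stoich) == 1,
        ))

    bm_stoich, _bm_formula = _biomass_reaction(spec)
    # biomass is a pseudo-species: its elemental content is defined by the
    # precursor drain (see biomass_carbon_content), not by a formula string
    model.add_metabolite(Metabolite(id="biomass_c0", name="biomass (1 g DW)"))
    model.add_reaction(Reaction(
        id="BIOMASS", name="biomass synthesis",
        stoichiometry=bm_stoich, lower_bound=0.0, upper_bound=_B,
    ))
    model.set_objective("BIOMASS")
    model.validate()
    _check_reference_growth(model)
    return model


def biomass_carbon_content(model: MetabolicModel) -> float:
    """mmol carbon drained into 1 g DW by the biomass reaction."""
    total = 0.0
    for met_id, coef in model.reaction("BIOMASS").stoichiometry.items():
        if met_id == "biomass_c0":
            continue
        total -= coef * model.metabolite(met_id).elements().get("C", 0)
    return total


def _check_reference_growth(model: MetabolicModel) -> None:
    """Raise with a precursor diagnostic if the model cannot grow on methane."""
    from .lp_engine import fba

    eb = {
        "EX_ch4_e0": (-constants.CH4_UPTAKE, -constants.CH4_UPTAKE),
        "ATPM": (constants.NGAM_ATP, constants.NGAM_ATP),
        "pMMO1": (0.0, 0.0),  # redox-arm reference condition
    }
    sol = fba(model, "BIOMASS", "maximize", eb)
    if sol.ok and sol.objective_value > 1e-9:
        return
    # diagnose which biomass precursor is blocked
    blocked = []
    for met_id, coef in model.reaction("BIOMASS").stoichiometry.items():
        if coef >= 0 or met_id in ("atp_c0", "h2o_c0"):
            continue
        probe = model.copy()
        probe.add_reaction(Reaction(
            id="_SINK", stoichiometry={met_id: -1.0},
            lower_bound=0.0, upper_bound=_B, is_exchange=True,
        ))
        psol = fba(probe, "_SINK", "maximize", eb)
        if not psol.ok or psol.objective_value <= 1e-9:
            blocked.append(met_id)
    raise RuntimeError(
        "core model cannot grow at the reference methane/NGAM constraints; "
        f"blocked biomass precursor(s): {blocked or 'none (energy-limited)'}"
    )


# ---------------------------------------------------------------------------
# Random networks
# ---------------------------------------------------------------------------

def random_network(
    n_metabolites: int,
    n_reactions: int,
    seed: int,
    mode: str = "pathway",
    degree_exponent: float = 2.5,
    max_retries: int = 20,
) -> MetabolicModel:
    """Reproducible random stoichiometric network.

    ``mode="pathway"`` builds a connected, bounded, mass-consistent network
    (every internal reaction conserves total coefficient mass, so the
    all-ones vector certifies stoichiometric consistency) with one source
    and one sink exchange — the substrate for brute-force LP cross-checks.

    ``mode="scale_free"`` samples metabolite degrees from a truncated
    power law P(k) ~ k^-degree_exponent and wires stubs into random
    reactions — the substrate for degree-distribution recovery tests; the
    generating exponent is well defined by construction.
    """
    if n_metabolites < 2 or n_reactions < 2:
        raise ValueError("need at least 2 metabolites and 2 reactions")
    rng = np.random.default_rng(seed)
    for attempt in range(max_retries):
        try:
            if mode == "pathway":
                return _pathway_network(n_metabolites, n_reactions, rng)
            if mode == "scale_free":
                return _scale_free_network(n_metabolites, degree_exponent, rng)
            raise ValueError(f"unknown mode {mode!r}")
        except _RetryGeneration:
            continue
    raise RuntimeError(
        f"could not generate a valid network in {max_retries} attempts "
        f"(n_metabolites={n_metabolites}, n_reactions={n_reactions})"
    )


class _RetryGeneration(Exception):
    pass


def _pathway_network(n_met: int, n_rxn: int, rng: np.random.Generator) -> MetabolicModel:
    met_ids = [f"M{i}_c0" for i in range(n_met)]
    mets = [Metabolite(id=m, formula="C") for m in met_ids]
    reactions: list[Reaction] = []

    # source on M0 and sink on the last metabolite
    cap = float(rng.integers(2, 11))
    reactions.append(Reaction(
        id="EX_src", stoichiometry={met_ids[0]: -1.0},
        lower_bound=-cap, upper_bound=0.0, is_exchange=True,
    ))
    reactions.append(Reaction(
        id="EX_snk", stoichiometry={met_ids[-1]: -1.0},
        lower_bound=0.0, upper_bound=float(rng.integers(2, 11)),
        is_exchange=True,
    ))

    n_internal = n_rxn - 2
    if n_internal < 1:
        raise _RetryGeneration
    # a spanning chain guarantees connectivity and a source->sink path
    chain_len = min(n_met - 1, n_internal)
    used = 0
    # pick chain waypoints covering M0 .. M_last
    idx = np.linspace(0, n_met - 1, chain_len + 1).round().astype(int)
    if len(set(idx)) != chain_len + 1:
        raise _RetryGeneration
    for k in range(chain_len):
        rev = bool(rng.random() < 0.3)
        ub = float(rng.integers(1, 11))
        reactions.append(Reaction(
            id=f"R{used}",
            stoichiometry={met_ids[idx[k]]: -1.0, met_ids[idx[k + 1]]: 1.0},
            lower_bound=-ub if rev else 0.0, upper_bound=ub,
        ))
        used += 1
    # extra random mass-conserving conversions
    while used < n_internal:
        n_sub = int(rng.integers(1, 3))
        n_prod = int(rng.integers(1, 3))
        picks = rng.choice(n_met, size=n_sub + n_prod, replace=False)
        subs, prods = picks[:n_sub], picks[n_sub:]
        stoich = {met_ids[i]: -1.0 for i in subs}
        # distribute substrate mass over products (unit masses)
        share = n_sub / n_prod
        for i in prods:
            stoich[met_ids[i]] = share
        rev = bool(rng.random() < 0.3)
        ub = float(rng.integers(1, 11))
        reactions.append(Reaction(
            id=f"R{used}", stoichiometry=stoich,
            lower_bound=-ub if rev else 0.0, upper_bound=ub,
        ))
        used += 1

    model = MetabolicModel(id="random_pathway", metabolites=mets, reactions=reactions)
    model.validate()
    return model


def _scale_free_network(
    n_met: int, gamma: float, rng: np.random.Generator, k_max: int = 60
) -> MetabolicModel:
    ks = np.arange(1, k_max + 1)
    p = ks.astype(float) ** (-gamma)
    p /= p.sum()
    degrees = rng.choice(ks, size=n_met, p=p)

    met_ids = [f"M{i}_c0" for i in range(n_met)]
    mets = [Metabolite(id=m, formula="C") for m in met_ids]
    stubs = np.repeat(np.arange(n_met), degrees)
    rng.shuffle(stubs)

    reactions: list[Reaction] = []
    rxn_size = 4  # average participants per reaction
    pos = 0
    r = 0
    while pos < len(stubs):
        group = stubs[pos:pos + rxn_size]
        pos += rxn_size
        uniq = list(dict.fromkeys(group.tolist()))
        if len(uniq) < 2:
            continue
        half = max(1, len(uniq) // 2)
        stoich = {met_ids[i]: -1.0 for i in uniq[:half]}
        stoich.update({met_ids[i]: 1.0 for i in uniq[half:]})
        reactions.append(Reaction(
            id=f"R{r}", stoichiometry=stoich,
            lower_bound=-1.0, upper_bound=1.0,
        ))
        r += 1
    if r < 2:
        raise _RetryGeneration
    # contract: at least one source and one sink exchange
    reactions.append(Reaction(
        id="EX_src", stoichiometry={met_ids[0]: -1.0},
        lower_bound=-1.0, upper_bound=0.0, is_exchange=True,
    ))
    reactions.append(Reaction(
        id="EX_snk", stoichiometry={met_ids[1]: -1.0},
        lower_bound=0.0, upper_bound=1.0, is_exchange=True,
    ))
    model = MetabolicModel(id="random_scale_free", metabolites=mets,
                           reactions=reactions)
    model.validate()
    return model
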