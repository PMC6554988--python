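"""Measured reference values used as scenario constraints.

These are experimental inputs (chemostat-free serum-bottle measurements on
Methylocystis parvus OBBP), not model outputs: specific methane uptake,
endogenous respiration converted to a non-growth maintenance ATP demand,
doubling-time-derived growth rates, and the bottle totals of the
methane/PHB co-consumption experiment.
"""

#: Specific methane uptake during balanced growth, mmol g-DW^-1 h^-1.
CH4_UPTAKE = 14.9

#: Endogenous respiration after methane depletion, mmol O2 g-DW^-1 h^-1.
ENDOGENOUS_RESPIRATION_O2 = 0.71

#: Assumed P/O-type coupling: mol ATP per mol O2 respired.
ATP_PER_O2 = 5.0

#: Non-growth-associated maintenance, mmol ATP g-DW^-1 h^-1 (= 0.71 * 5).
NGAM_ATP = 3.5

#: Doubling time on methane, h, and the corresponding growth rate, h^-1.
DOUBLING_TIME_CH4 = 6.45
GROWTH_RATE_CH4 = 0.107

#: Growth rate during the first duplication under methane/PHB co-consumption.
GROWTH_RATE_COCONSUMPTION = 0.154

#: Observed biomass yield on methane, g-DW per mol CH4.
YIELD_ON_CH4 = 7.2

#: Observed molar oxygen/methane consumption ratio.
O2_PER_CH4 = 1.5

#: Co-consumption bottle experiment: 50 mL liquid medium, 15 h duration.
BOTTLE_LIQUID_VOLUME_L = 0.050
BOTTLE_DURATION_H = 15.0
BOTTLE_CH4_MMOL = 1.8
BOTTLE_O2_MMOL = 2.6
BOTTLE_PHB_INITIAL_G_L = 0.16
BOTTLE_PHB_FINAL_G_L = 0.017
BOTTLE_BIOMASS_INITIAL_G_L = 0.27
BOTTLE_BIOMASS_FINAL_G_L = 0.69

#: PHB monomer-equivalent molar mass, g/mol: 3-hydroxybutyrate (C4H8O3,
#: 104.10 g/mol) minus one water (18.02 g/mol), i.e. the repeating unit.
PHB_MONOMER_MASS = 86.09
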