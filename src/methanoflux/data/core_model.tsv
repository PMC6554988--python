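id	name	equation	lower_bound	upper_bound	gene_association	ec_numbers
EX_ch4_e0	methane exchange	ch4_e0 <=>	-1000.0	1000.0		
EX_o2_e0	oxygen exchange	o2_e0 <=>	-1000.0	1000.0		
EX_co2_e0	CO2 exchange	co2_e0 <=>	-1000.0	1000.0		
EX_nh4_e0	ammonium exchange	nh4_e0 <=>	-1000.0	1000.0		
EX_no3_e0	nitrate exchange	no3_e0 ->	0.0	0.0		
EX_n2_e0	dinitrogen exchange	n2_e0 ->	0.0	1000.0		
EX_ac_e0	acetate exchange	ac_e0 ->	0.0	1000.0		
EX_btd_e0	butane-2,3-diol exchange	btd_e0 ->	0.0	1000.0		
EX_h2o_e0	water exchange	h2o_e0 <=>	-1000.0	1000.0		
EX_h_c0	proton sink/source	h_c0 <=>	-1000.0	1000.0		
EX_phb_c0	PHB granule storage boundary	phb_c0 ->	0.0	1000.0		
EX_biomass_c0	biomass sink	biomass_c0 ->	0.0	1000.0		
T_ch4	methane diffusion	ch4_e0 <=> ch4_c0	-1000.0	1000.0		
T_o2	oxygen diffusion	o2_e0 <=> o2_c0	-1000.0	1000.0		
T_co2	CO2 diffusion	co2_e0 <=> co2_c0	-1000.0	1000.0		
T_nh4	ammonium transport	nh4_e0 <=> nh4_c0	-1000.0	1000.0		
T_no3	nitrate transport	no3_e0 <=> no3_c0	-1000.0	1000.0		
T_n2	dinitrogen diffusion	n2_c0 <=> n2_e0	-1000.0	1000.0		
T_ac	acetate transport	ac_c0 <=> ac_e0	-1000.0	1000.0		
T_btd	butane-2,3-diol transport	btd_c0 <=> btd_e0	-1000.0	1000.0		
T_h2o	water diffusion	h2o_e0 <=> h2o_c0	-1000.0	1000.0		
pMMO1	pMMO (cytochrome-c coupled)	ch4_c0 + o2_c0 + 2 cytcred_c0 -> meoh_c0 + h2o_c0 + 2 cytcox_c0	0.0	1000.0		
pMMO2	pMMO (ubiquinol coupled)	ch4_c0 + o2_c0 + q8h2_c0 -> meoh_c0 + h2o_c0 + q8_c0	0.0	1000.0		
MEDH	methanol dehydrogenase (cytochrome c)	meoh_c0 + 2 cytcox_c0 -> fald_c0 + 2 cytcred_c0	0.0	1000.0		
FALDH	formaldehyde dehydrogenase	fald_c0 + h2o_c0 + nad_c0 -> for_c0 + nadh_c0 + h_c0	0.0	1000.0		
FDH	formate dehydrogenase	for_c0 + nad_c0 -> co2_c0 + nadh_c0 + h_c0	0.0	1000.0		
FAE	formaldehyde-THF condensation	fald_c0 + thf_c0 -> mlthf_c0 + h2o_c0	0.0	1000.0		
SHMT	serine hydroxymethyltransferase	gly_c0 + mlthf_c0 + h2o_c0 -> ser_c0 + thf_c0	0.0	1000.0		
SGA	serine-glyoxylate aminotransferase	ser_c0 + glx_c0 -> hpyr_c0 + gly_c0	0.0	1000.0		
HPR	hydroxypyruvate reductase	hpyr_c0 + nadh_c0 + h_c0 -> glyc_c0 + nad_c0	0.0	1000.0		
GCK	glycerate kinase + enolase (lumped)	glyc_c0 + atp_c0 -> pep_c0 + adp_c0 + h2o_c0	0.0	1000.0		
PPC	PEP carboxylase	pep_c0 + co2_c0 + h2o_c0 -> oaa_c0 + pi_c0	0.0	1000.0		
MDH	malate dehydrogenase	oaa_c0 + nadh_c0 + h_c0 <=> mal_c0 + nad_c0	-1000.0	1000.0		
MTK	malate thiokinase	mal_c0 + coa_c0 + atp_c0 <=> malylcoa_c0 + adp_c0 + pi_c0	-1000.0	1000.0		
MCL1	malyl-CoA lyase (malyl-CoA cleavage)	malylcoa_c0 <=> glx_c0 + accoa_c0	-1000.0	1000.0		
GLYS	glycine synthase (reverse cleavage system)	co2_c0 + mlthf_c0 + nh4_c0 + nadh_c0 -> gly_c0 + thf_c0 + nad_c0	0.0	1000.0		
GCL	glyoxylate carboligase	2 glx_c0 -> tsa_c0 + co2_c0	0.0	1000.0		
TSR	tartronate semialdehyde reductase	tsa_c0 + nadh_c0 + h_c0 -> glyc_c0 + nad_c0	0.0	1000.0		
SPT	serine-pyruvate aminotransferase	ser_c0 + pyr_c0 -> hpyr_c0 + ala_c0	0.0	1000.0		
ALD	alanine dehydrogenase	ala_c0 + h2o_c0 + nad_c0 -> pyr_c0 + nh4_c0 + nadh_c0	0.0	1000.0		
CS	citrate synthase	accoa_c0 + oaa_c0 + h2o_c0 -> cit_c0 + coa_c0	0.0	1000.0		
ACO	aconitase	cit_c0 <=> icit_c0	-1000.0	1000.0		
ICD	isocitrate dehydrogenase	icit_c0 + nad_c0 -> akg_c0 + co2_c0 + nadh_c0 + h_c0	0.0	1000.0		
AKGDH	alpha-ketoglutarate dehydrogenase	akg_c0 + coa_c0 + nad_c0 -> succoa_c0 + co2_c0 + nadh_c0 + h_c0	0.0	1000.0		
SCS	succinyl-CoA synthetase	succoa_c0 + adp_c0 + pi_c0 <=> succ_c0 + coa_c0 + atp_c0	-1000.0	1000.0		
SDH	succinate dehydrogenase	succ_c0 + q8_c0 -> fum_c0 + q8h2_c0	0.0	1000.0		
FUM	fumarase	fum_c0 + h2o_c0 <=> mal_c0	-1000.0	1000.0		
CPLX1	NADH dehydrogenase (complex I)	nadh_c0 + q8_c0 + 5 h_c0 -> nad_c0 + q8h2_c0 + 4 hpm_p0	0.0	1000.0		
CPLX3	cytochrome bc1 (complex III)	q8h2_c0 + 2 cytcox_c0 + 2 h_c0 -> q8_c0 + 2 cytcred_c0 + 2 hpm_p0	0.0	1000.0		
CPLX4	cytochrome c oxidase (complex IV)	2 cytcred_c0 + 0.5 o2_c0 + 4 h_c0 -> 2 cytcox_c0 + h2o_c0 + 4 hpm_p0	0.0	1000.0		
ATPS	ATP synthase	adp_c0 + pi_c0 + 4 hpm_p0 <=> atp_c0 + h2o_c0 + 4 h_c0	-1000.0	1000.0		
ATPM	ATP maintenance (non-growth)	atp_c0 + h2o_c0 -> adp_c0 + pi_c0	0.0	1000.0		
PHAA	beta-ketothiolase	2 accoa_c0 <=> aacoa_c0 + coa_c0	-1000.0	1000.0		
PHAB	acetoacetyl-CoA reductase (synthesis-directed)	aacoa_c0 + nadh_c0 + h_c0 -> hbcoa_c0 + nad_c0	0.0	1000.0		
PHAC	PHB synthase	hbcoa_c0 -> phb_c0 + coa_c0	0.0	1000.0		
PHBTE	3-hydroxybutyryl-CoA thioesterase	hbcoa_c0 + h2o_c0 -> bhb_c0 + coa_c0	0.0	1000.0		
BDH1	3-hydroxybutyrate dehydrogenase	bhb_c0 + nad_c0 -> acac_c0 + nadh_c0 + h_c0	0.0	1000.0		
SCOT	succinyl-CoA:acetoacetate CoA-transferase	acac_c0 + succoa_c0 -> aacoa_c0 + succ_c0	0.0	1000.0		
PHBDEG	PHB depolymerase + 3HB-CoA ligation (lumped entry)	phb_c0 + coa_c0 + atp_c0 + h2o_c0 -> hbcoa_c0 + adp_c0 + pi_c0	0.0	1000.0		
EMCL	ethylmalonyl-CoA pathway (lumped to l-erythro-3-methylmalyl-CoA)	hbcoa_c0 + co2_c0 + nadh_c0 + h_c0 + q8_c0 -> mmalcoa_c0 + nad_c0 + q8h2_c0	0.0	1000.0		
MCL2	malyl-CoA lyase (methylmalyl-CoA cleavage)	mmalcoa_c0 <=> glx_c0 + ppcoa_c0	-1000.0	1000.0		
PCC	propionyl-CoA carboxylase + mutase (lumped)	ppcoa_c0 + co2_c0 + atp_c0 + h2o_c0 -> succoa_c0 + adp_c0 + pi_c0	0.0	1000.0		
PYK	pyruvate kinase	pep_c0 + adp_c0 -> pyr_c0 + atp_c0	0.0	1000.0		
PEPCK	PEP carboxykinase	oaa_c0 + atp_c0 -> pep_c0 + co2_c0 + adp_c0	0.0	1000.0		
POXB	pyruvate oxidase (quinone-linked)	pyr_c0 + h2o_c0 + q8_c0 -> ac_c0 + co2_c0 + q8h2_c0	0.0	1000.0		
ALS	acetolactate synthase	2 pyr_c0 -> alac_c0 + co2_c0	0.0	1000.0		
ALDC	acetolactate decarboxylase	alac_c0 -> actn_c0 + co2_c0	0.0	1000.0		
BDH	butanediol dehydrogenase	actn_c0 + nadh_c0 + h_c0 -> btd_c0 + nad_c0	0.0	1000.0		
PTA_ACK	phosphotransacetylase + acetate kinase (lumped)	accoa_c0 + adp_c0 + pi_c0 -> ac_c0 + atp_c0 + coa_c0	0.0	1000.0		
NAR	nitrate reductase	no3_c0 + q8h2_c0 -> no2_c0 + q8_c0 + h2o_c0	0.0	1000.0		
NIR	nitrite reductase	no2_c0 + cytcred_c0 + h_c0 -> no_c0 + cytcox_c0 + h2o_c0	0.0	1000.0		
NOR	nitric oxide reductase	2 no_c0 + 2 cytcred_c0 -> n2o_c0 + 2 cytcox_c0 + h2o_c0	0.0	1000.0		
NOS	nitrous oxide reductase	n2o_c0 + 2 cytcred_c0 -> n2_c0 + 2 cytcox_c0 + h2o_c0	0.0	1000.0		
BIOMASS	biomass synthesis	10.794756 accoa_c0 + 5.397378 ser_c0 + 3.9580772 akg_c0 + 6.4768536 oaa_c0 + 21.589512 nh4_c0 + 5.0375528 nadh_c0 + 40 atp_c0 + 40 h2o_c0 -> 10.794756 coa_c0 + 5.0375528 nad_c0 + 40 adp_c0 + 40 pi_c0 + biomass_c0	0.0	1000.0		
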