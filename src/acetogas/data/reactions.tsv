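id	name	equation	lower_bound	upper_bound	tags
EX_co	CO exchange	-1:co_c	-1000	1000	exchange
EX_h2	H2 exchange	-1:h2_c	-1000	1000	exchange
EX_co2	CO2 exchange	-1:co2_c	-1000	1000	exchange
EX_etoh	ethanol exchange	-1:etoh_c	0	1000	exchange
EX_ac	acetate exchange	-1:ac_c	0	1000	exchange
EX_bdo	2,3-BDO exchange	-1:bdo_c	0	1000	exchange
EX_biomass	biomass drain	-1:biomass_c	0	1000	exchange
EX_nh3	NH3 uptake	-1:nh3_c	-1000	0	exchange
EX_h2o	water exchange	-1:h2o_c	-1000	1000	exchange
EX_h	proton exchange	-1:h_c	-1000	1000	exchange
CODH	CO dehydrogenase	1:co2_c -1:co_c -1:fd_ox_c 1:fd_red_c -1:h2o_c 2:h_c	-1000	1000	
ACS	acetyl-CoA synthase (CODH/ACS)	-1:5mthf_c 1:accoa_c -1:co_c -1:coa_c 1:h_c 1:thf_c	0	1000	
rxn00103_c0	formate dehydrogenase (NADPH, redox-consuming)	-1:co2_c 1:for_c 1:nadp_c -1:nadph_c	0	1000	
rxn08518_c0	formate-H2 lyase (direct CO2 reduction with H2)	-1:co2_c 1:for_c -1:h2_c 1:h_c	0	1000	
leq000001	electron-bifurcating hydrogenase (Fd_red + NADPH from 2 H2)	-1:fd_ox_c 1:fd_red_c -2:h2_c 3:h_c -1:nadp_c 1:nadph_c	0	1000	
FTHFS	formyl-THF synthetase	1:10fthf_c 1:adp_c -1:atp_c -1:for_c 1:pi_c -1:thf_c	0	1000	
MTHFC	methenyl-THF cyclohydrolase	-1:10fthf_c 1:h2o_c -1:h_c 1:methf_c	0	1000	
MTHFD	methylene-THF dehydrogenase (NADH)	-1:methf_c 1:mlthf_c 1:nad_c -1:nadh_c	0	1000	
MTHFR_fd	methylene-THF reductase (electron-bifurcating, Fd-reducing)	1:5mthf_c -1:fd_ox_c 1:fd_red_c -1:h_c -1:mlthf_c 2:nad_c -2:nadh_c	0	1000	variant:metfv
MTHFR_nadh	methylene-THF reductase (NADH only)	1:5mthf_c -2:h_c -1:mlthf_c 1:nad_c -1:nadh_c	0	0	variant:metfv
PTA	phosphotransacetylase	-1:accoa_c 1:actp_c 1:coa_c -1:pi_c	-1000	1000	
ACKA	acetate kinase	1:ac_c -1:actp_c -1:adp_c 1:atp_c	-1000	1000	
ACALD	acetaldehyde dehydrogenase (AdhE, acylating)	1:acald_c -1:accoa_c 1:coa_c -1:h_c 1:nad_c -1:nadh_c	-1000	1000	
AOR	acetaldehyde:ferredoxin oxidoreductase	-1:ac_c 1:acald_c 1:fd_ox_c -1:fd_red_c 1:h2o_c -3:h_c	0	1000	
ADH	alcohol dehydrogenase	-1:acald_c 1:etoh_c -1:h_c 1:nad_c -1:nadh_c	-1000	1000	
PFOR	pyruvate:ferredoxin oxidoreductase (synthase direction)	-1:accoa_c -1:co2_c 1:coa_c 1:fd_ox_c -1:fd_red_c -1:h_c 1:pyr_c	0	1000	
ALS	acetolactate synthase	1:alac_c 1:co2_c -1:h_c -2:pyr_c	0	1000	
ALDC	acetolactate decarboxylase	1:actn_c -1:alac_c 1:co2_c -1:h_c	0	1000	
BDH	2,3-butanediol dehydrogenase (NADPH)	-1:actn_c 1:bdo_c -1:h_c 1:nadp_c -1:nadph_c	0	1000	
NFN	Nfn transhydrogenase (electron-bifurcating)	1:fd_ox_c -1:fd_red_c -1:h_c 1:nad_c -1:nadh_c -2:nadp_c 2:nadph_c	-1000	1000	
RNF	Rnf ferredoxin:NAD+ oxidoreductase (proton pumping)	1:fd_ox_c -1:fd_red_c -3:h_c 2:h_e -1:nad_c 1:nadh_c	0	1000	
ATPS	ATP synthase	-1:adp_c 1:atp_c 1:h2o_c 3:h_c -4:h_e -1:pi_c	0	1000	
ATPM	ATP maintenance dissipation	1:adp_c -1:atp_c -1:h2o_c 1:h_c 1:pi_c	0	1000	maintenance
BIOMASS	biomass synthesis (1 C-mol drain)	-0.5:accoa_c 2:adp_c -2:atp_c 1:biomass_c 0.5:coa_c -2:h2o_c 1.9:h_c 0.1:nadp_c -0.1:nadph_c -0.2:nh3_c 2:pi_c	0	1000	
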