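id	name	formula	charge	compartment
co_c	carbon monoxide	CO	0	c
co2_c	carbon dioxide	CO2	0	c
h2_c	hydrogen	H2	0	c
h2o_c	water	H2O	0	c
h_c	proton (cytosol)	H	1	c
h_e	proton (periplasm)	H	1	e
nh3_c	ammonia	H3N	0	c
fd_ox_c	oxidised ferredoxin	Fd	0	c
fd_red_c	reduced ferredoxin	Fd	-2	c
nad_c	NAD+	C21H26N7O14P2	-1	c
nadh_c	NADH	C21H27N7O14P2	-2	c
nadp_c	NADP+	C21H25N7O17P3	-3	c
nadph_c	NADPH	C21H26N7O17P3	-4	c
atp_c	ATP	C10H12N5O13P3	-4	c
adp_c	ADP	C10H12N5O10P2	-3	c
pi_c	phosphate	HO4P	-2	c
for_c	formate	CHO2	-1	c
thf_c	tetrahydrofolate	C19H21N7O6	-2	c
10fthf_c	10-formyl-THF	C20H21N7O7	-2	c
methf_c	5,10-methenyl-THF	C20H20N7O6	-1	c
mlthf_c	5,10-methylene-THF	C20H21N7O6	-2	c
5mthf_c	5-methyl-THF	C20H24N7O6	-1	c
coa_c	coenzyme A	C21H32N7O16P3S	-4	c
accoa_c	acetyl-CoA	C23H34N7O17P3S	-4	c
actp_c	acetyl phosphate	C2H3O5P	-2	c
ac_c	acetate	C2H3O2	-1	c
acald_c	acetaldehyde	C2H4O	0	c
etoh_c	ethanol	C2H6O	0	c
pyr_c	pyruvate	C3H3O3	-1	c
alac_c	2-acetolactate	C5H7O4	-1	c
actn_c	acetoin	C4H8O2	0	c
bdo_c	2,3-butanediol	C4H10O2	0	c
biomass_c	biomass (1 C-mol)	CH1.8N0.2O0.5	0	c
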