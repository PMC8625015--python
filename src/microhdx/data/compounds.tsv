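# Reference compound panel for microdroplet-HDX simulations.
# exchange_sites: semicolon-separated class:count pairs (empty = no labile proton).
# charge_site_exchange: whether the charging proton of a proton-bearing adduct
#   is available for exchange on top of the listed sites.
# hdx_attenuation: compound-specific multiplier on all effective exchange
#   probabilities (models differential liquid-phase back exchange).
name	formula	adduct	exchange_sites	charge_site_exchange	hdx_attenuation	abundance
codeine	C18H21NO3	[M+H]+	hydroxyl:1	true	1.0	1.0
hydrocodone	C18H21NO3	[M+H]+		true	1.0	1.0
6-acetylmorphine	C19H21NO4	[M+H]+	phenol:1	true	1.0	1.0
naloxone	C19H21NO4	[M+H]+	phenol:1;hydroxyl:1	true	1.0	1.0
morphine	C17H19NO3	[M+H]+	phenol:1;hydroxyl:1	true	0.65	1.0
norcodeine	C17H19NO3	[M+H]+	hydroxyl:1;imine_NH:1	true	1.0	1.0
glucose	C6H12O6	[M+H]+	hydroxyl:5	false	1.0	3.0
inositol	C6H12O6	[M+H]+	hydroxyl:6	false	1.0	2.0
urea	CH4N2O	[2M+H]+	amide_NH:4	true	1.0	5.0
creatinine	C4H7N3O	[M+H]+	amine:1;amide_NH:2	true	1.0	4.0
sphingosine	C18H37NO2	[M+H]+	hydroxyl:2;amine:2	false	1.0	0.5
palmitoylethanolamide	C18H37NO2	[M+Na]+	hydroxyl:1;amide_NH:1	true	1.0	0.5
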