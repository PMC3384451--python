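# name: simplified_network
# objective: ATPM
id	equation	lb	ub	enzymatic	exchange
R_glycolysis	1 glc -> 2 accoa + 2 atp + 2 co2 + 2 nadh	0	1e+08	true	false
R_acetate	1 accoa -> 1 ac + 1 atp	0	1e+08	true	false
R_waste	1 accoa + 2 nadh -> 1 waste	0	1e+08	true	false
R_tca	1 accoa -> 1 atp + 2 co2 + 4 nadh	0	1e+08	true	false
R_oxphos	1 nadh + 0.5 o2 -> 2 atp	0	1e+08	true	false
EX_glc	1 glc -> 	-10	0	false	true
EX_o2	1 o2 -> 	-1e+08	0	false	true
EX_ac	1 ac -> 	0	1e+08	false	true
EX_waste	1 waste -> 	0	1e+08	false	true
EX_co2	1 co2 -> 	0	1e+08	false	true
ATPM	1 atp -> 	0	1e+08	false	true
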