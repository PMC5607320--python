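# Synthetic, illustrative cholesterol transfer-coefficient table.
# kappa(c) is the dimensionless (beta-scaled) transfer free-energy gain per
# A^2 of hydrophobic surface exposed to a membrane with cholesterol mole
# fraction c, relative to the cholesterol-free membrane. These numbers are a
# plausible monotone anchor for demonstrations and tests; they are NOT
# measured partition data. Supply your own table for quantitative work.
cholesterol_fraction	kappa_per_A2
0.0	0.0
0.1	0.0024
0.2	0.0048
0.3	0.0072
0.4	0.0096
0.5	0.0120
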