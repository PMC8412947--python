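# Synthetic reconstruction of the classic whole-muscle load-efficiency
# experiment (see mtulab.efficiency.synthesize_load_efficiency_table).
# a_over_P0 = 0.25
p,eta
0.00,0.000000
0.05,0.167815
0.10,0.266509
0.15,0.329926
0.20,0.372700
0.25,0.402145
0.30,0.422280
0.35,0.435448
0.40,0.443050
0.45,0.445906
0.50,0.444444
0.55,0.438791
0.60,0.428801
0.65,0.414050
0.70,0.393775
0.75,0.366748
0.80,0.331057
0.85,0.283680
0.90,0.219673
0.95,0.130477
1.00,0.000000
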