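# Average myofibre rotation angles (degrees) at endocardium and epicardium
# per AHA17 segment, plus the single pair used for the right ventricle.
# Segment 4's epicardial angle of 0 is an outlier among the -20..-40 values
# of the other segments; it is kept verbatim from the source averages.
segment,theta_endo_deg,theta_epi_deg
1,20,-20
2,40,-40
3,30,-40
4,40,0
5,60,-20
6,40,-20
7,40,-40
8,60,-40
9,30,-30
10,40,-20
11,60,-20
12,40,-40
13,60,-40
14,30,-30
15,80,-20
16,60,-40
17,10,-10
RV,40,-30
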