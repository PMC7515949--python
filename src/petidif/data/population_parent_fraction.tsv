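time_s	parent_fraction
# Synthetic placeholder population parent-fraction table with the typical
# shape for a TSPO tracer (unity at injection, ~40% parent at one hour).
# Replace with a measured population curve for real studies.
0	1.00
120	0.97
300	0.90
600	0.79
900	0.70
1200	0.63
1800	0.54
2400	0.48
3000	0.43
3600	0.40
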