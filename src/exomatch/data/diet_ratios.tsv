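# Molar dietary amino-acid ratios for the chemically defined (holidic) fly diets:
# FLYAA     exome-matched ratio (unweighted average over all fly proteins)
# MALEAA    whole-body male transcriptome-weighted ratio
# FEMALEAA  whole-body female transcriptome-weighted ratio
# Printed to 3 decimals; columns renormalize to 1 on load.
aa	FLYAA	MALEAA	FEMALEAA
A	0.075	0.079	0.078
C	0.017	0.019	0.016
D	0.053	0.049	0.051
E	0.063	0.059	0.062
F	0.037	0.039	0.036
G	0.062	0.068	0.068
H	0.026	0.023	0.024
I	0.052	0.056	0.054
K	0.057	0.062	0.068
L	0.094	0.093	0.088
M	0.025	0.026	0.024
N	0.047	0.047	0.047
P	0.052	0.052	0.049
Q	0.046	0.044	0.046
R	0.057	0.051	0.055
S	0.079	0.075	0.074
T	0.056	0.054	0.055
V	0.062	0.063	0.064
W	0.010	0.012	0.011
Y	0.031	0.030	0.030
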