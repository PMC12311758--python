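label,x,y,z
Fpz,0.000000,0.951057,0.309017
Fp2,0.293893,0.904508,0.309017
AF8,0.559017,0.769421,0.309017
F8,0.769421,0.559017,0.309017
FT8,0.904508,0.293893,0.309017
T8,0.951057,0.000000,0.309017
TP8,0.904508,-0.293893,0.309017
P8,0.769421,-0.559017,0.309017
PO8,0.559017,-0.769421,0.309017
O2,0.293893,-0.904508,0.309017
Oz,0.000000,-0.951057,0.309017
O1,-0.293893,-0.904508,0.309017
PO7,-0.559017,-0.769421,0.309017
P7,-0.769421,-0.559017,0.309017
TP7,-0.904508,-0.293893,0.309017
T7,-0.951057,0.000000,0.309017
FT7,-0.904508,0.293893,0.309017
F7,-0.769421,0.559017,0.309017
AF7,-0.559017,0.769421,0.309017
Fp1,-0.293893,0.904508,0.309017
AFz,0.000000,0.809017,0.587785
Fz,0.000000,0.587785,0.809017
FCz,0.000000,0.309017,0.951057
Cz,0.000000,0.000000,1.000000
CPz,0.000000,-0.309017,0.951057
Pz,0.000000,-0.587785,0.809017
POz,0.000000,-0.809017,0.587785
AF3,-0.294292,0.830962,0.472118
AF4,0.294292,0.830962,0.472118
F5,-0.618731,0.619753,0.482782
F6,0.618731,0.619753,0.482782
F3,-0.433027,0.645416,0.629226
F4,0.433027,0.645416,0.629226
F1,-0.222818,0.634556,0.740062
F2,0.222818,0.634556,0.740062
FC5,-0.756469,0.342798,0.556996
FC6,0.756469,0.342798,0.556996
FC3,-0.543523,0.362291,0.757184
FC4,0.543523,0.362291,0.757184
FC1,-0.283943,0.350699,0.892405
FC2,0.283943,0.350699,0.892405
C5,-0.809017,0.000000,0.587785
C6,0.809017,0.000000,0.587785
C3,-0.587785,0.000000,0.809017
C4,0.587785,0.000000,0.809017
C1,-0.309017,0.000000,0.951057
C2,0.309017,0.000000,0.951057
CP5,-0.756469,-0.342798,0.556996
CP6,0.756469,-0.342798,0.556996
CP3,-0.543523,-0.362291,0.757184
CP4,0.543523,-0.362291,0.757184
CP1,-0.283943,-0.350699,0.892405
CP2,0.283943,-0.350699,0.892405
P5,-0.618731,-0.619753,0.482782
P6,0.618731,-0.619753,0.482782
P3,-0.433027,-0.645416,0.629226
P4,0.433027,-0.645416,0.629226
P1,-0.222818,-0.634556,0.740062
P2,0.222818,-0.634556,0.740062
PO3,-0.294292,-0.830962,0.472118
PO4,0.294292,-0.830962,0.472118
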