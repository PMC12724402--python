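name,x,y
Fp1,-0.0933,0.9
AF7,-0.5278,0.74
AF3,-0.2561,0.74
F1,-0.1463,0.56
F3,-0.3018,0.56
F5,-0.4573,0.56
F7,-0.6219,0.56
FT7,-0.702,0.29
FC5,-0.5162,0.29
FC3,-0.3407,0.29
FC1,-0.1652,0.29
C1,-0.1716,0.0
C3,-0.3539,0.0
C5,-0.5362,0.0
T7,-0.9115,0.0
TP7,-0.702,-0.29
CP5,-0.5162,-0.29
CP3,-0.3407,-0.29
CP1,-0.1652,-0.29
P1,-0.1463,-0.56
P3,-0.3018,-0.56
P5,-0.4573,-0.56
P7,-0.6219,-0.56
P9,-0.7499,-0.56
PO7,-0.5278,-0.74
PO3,-0.2561,-0.74
O1,-0.0933,-0.9
Iz,0.0,-1.0
Oz,0.0,-0.9
POz,0.0,-0.74
Pz,0.0,-0.56
CPz,0.0,-0.29
Fpz,0.0,0.9
Fp2,0.0933,0.9
AF8,0.5278,0.74
AF4,0.2561,0.74
AFz,0.0,0.74
Fz,0.0,0.56
F2,0.1463,0.56
F4,0.3018,0.56
F6,0.4573,0.56
F8,0.6219,0.56
FT8,0.702,0.29
FC6,0.5162,0.29
FC4,0.3407,0.29
FC2,0.1652,0.29
FCz,0.0,0.29
Cz,0.0,0.0
C2,0.1716,0.0
C4,0.3539,0.0
C6,0.5362,0.0
T8,0.9115,0.0
TP8,0.702,-0.29
CP6,0.5162,-0.29
CP4,0.3407,-0.29
CP2,0.1652,-0.29
P2,0.1463,-0.56
P4,0.3018,-0.56
P6,0.4573,-0.56
P8,0.6219,-0.56
P10,0.7499,-0.56
PO8,0.5278,-0.74
PO4,0.2561,-0.74
O2,0.0933,-0.9
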