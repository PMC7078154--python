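# Vertical excitation fixture: 19 excited singlets + 17 triplets of the
# Trp/Re(CO)3(Dmp)(His) model system (TDA-B3LYP).
# CT columns are hole->electron fragment-pair percentages; "others" collects
# the remaining weight.  A few percentages are ambiguous in the source
# typography; dominant characters follow the published assignment.
label,mult,E_eV,fosc,trp_trp,trp_dmp,trp_re,his_dmp,dmp_dmp,re_dmp,re_re,others,character
S1,1,2.71,0.001,0,92,5,0,1,0,0,1,CS
S2,1,2.83,0.011,1,96,1,0,1,0,0,0,CS
S3,1,3.22,0.003,0,3,0,12,5,71,6,3,MLCT
S4,1,3.27,0.011,0,79,4,1,8,6,0,2,CS
S5,1,3.39,0.007,1,93,1,1,4,0,0,0,CS
S6,1,3.44,0.008,0,6,0,8,13,69,2,2,MLCT
S7,1,3.57,0.064,0,0,0,3,5,82,7,2,MLCT
S8,1,3.60,0.107,0,2,0,4,10,75,6,3,MLCT
S9,1,3.73,0.042,0,1,0,2,18,77,1,1,MLCT
S10,1,3.77,0.000,0,1,0,84,2,4,0,9,LLCT
S11,1,3.86,0.003,0,0,0,0,5,93,1,1,MLCT
S12,1,3.97,0.016,0,1,0,76,1,3,8,12,LLCT
S13,1,4.04,0.003,1,86,8,1,2,0,0,1,CS
S14,1,4.09,0.002,0,4,0,1,46,0,16,24,IL
S15,1,4.21,0.001,0,10,73,0,0,0,2,13,AMCS
S16,1,4.25,0.003,0,6,0,1,76,13,0,3,IL
S17,1,4.28,0.032,0,0,1,1,1,9,72,15,MC
S18,1,4.33,0.001,0,0,1,0,1,9,71,17,MC
S19,1,4.39,0.001,0,0,0,2,3,20,62,12,MC
T1,3,2.70,0.0,1,89,5,0,3,0,0,1,CS
T2,3,2.79,0.0,3,90,0,0,6,0,0,0,CS
T3,3,2.99,0.0,0,11,0,2,56,2,6,22,IL
T4,3,3.03,0.0,0,15,1,1,54,2,2,24,IL
T5,3,3.16,0.0,0,11,0,6,28,47,5,3,MLCT
T6,3,3.31,0.0,1,68,4,1,6,17,2,2,CS
T7,3,3.42,0.0,1,1,1,8,11,67,1,1,MLCT
T8,3,3.44,0.0,11,58,0,3,1,0,17,1,CS
T9,3,3.47,0.0,83,1,2,0,0,1,1,2,AC
T10,3,3.53,0.0,0,2,0,0,7,77,1,13,MLCT
T11,3,3.62,0.0,0,20,2,3,62,6,1,6,IL
T12,3,3.67,0.0,0,7,0,1,39,41,8,4,MLCT
T13,3,3.79,0.0,0,2,0,46,19,2,6,26,LLCT
T14,3,3.81,0.0,0,2,0,18,21,55,1,3,MLCT
T15,3,3.85,0.0,0,2,0,14,78,3,1,2,IL
T16,3,3.88,0.0,0,0,0,1,2,10,70,16,MC
T17,3,4.03,0.0,0,1,0,1,16,80,1,1,MLCT
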