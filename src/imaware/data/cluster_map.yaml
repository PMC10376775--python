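# Electrode -> cluster assignment (nine areas; midline 'z' electrodes
# form the sagittal cluster S). Reconstructed from 10/20 name prefixes;
# review before any real-data use.
AF3: AF
AF4: AF
AF7: AF
AF8: AF
AFz: S
C1: C
C2: C
C3: C
C4: C
C5: C
C6: C
CP1: CP
CP2: CP
CP3: CP
CP4: CP
CP5: CP
CP6: CP
CPz: S
Cz: S
F1: F
F2: F
F3: F
F4: F
F5: F
F6: F
F7: F
F8: F
FC1: FC
FC2: FC
FC3: FC
FC4: FC
FC5: FC
FC6: FC
FCz: S
FT10: T
FT7: T
FT8: T
FT9: T
Fp1: AF
Fp2: AF
Fz: S
O1: PO
O2: PO
Oz: S
P1: P
P2: P
P3: P
P4: P
P5: P
P6: P
P7: P
P8: P
PO10: PO
PO3: PO
PO4: PO
PO7: PO
PO8: PO
PO9: PO
POz: S
Pz: S
T7: T
T8: T
TP7: T
TP8: T
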