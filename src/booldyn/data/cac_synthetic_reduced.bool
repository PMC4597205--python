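# Reduced form of the SYNTHETIC CAC-style model under the pro-tumour
# scenario (DC clamped ON, other immune cells OFF, APC ON), produced by
# booldyn's reduction pipeline (constant propagation, mediator removal,
# dangling removal; Proliferation and Apoptosis protected).  Regenerable via:
#   booldyn reduce --model cac_synthetic --scenario pro_tumor_dc \
#           --protect Proliferation,Apoptosis --out reduced.bool
STAT3* = not STAT3
IKK* = AKT and STAT3
NFKB* = IKK
COX2* = NFKB or STAT3
AKT* = not P53
GSK3B* = not AKT
P53* = (COX2 or P53) and not MDM2
MDM2* = (P53 or AKT) and not GSK3B
CYCLIND1* = (not GSK3B or STAT3) and not GSK3B
BCL2* = AKT or NFKB
BAX* = P53 and not BCL2
MOMP* = BAX and not BCL2
IAP* = NFKB and not MOMP
CASP9* = MOMP and not IAP
CASP3* = CASP9 and not IAP
Proliferation* = CYCLIND1 and not P53
Apoptosis* = CASP3
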