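# SYNTHETIC colitis-associated colon cancer (CAC) style signalling model.
# A stand-in demonstration network assembled from textbook pathway logic
# (IL6/JAK/STAT3, TNF/NF-kB, COX2/PGE2, ERK MAPK, PI3K/AKT, P53/MDM2,
# sphingolipid rheostat, mitochondrial apoptosis); NOT a transcription of any
# published curated model.  Immune microenvironment nodes are self-maintaining
# inputs toggled by scenarios; Proliferation and Apoptosis are the readouts.

# --- immune microenvironment (inputs; DC deactivates under IL10 tone) ---
DC* = DC and not IL10
MAC* = MAC
TREG* = TREG
CTL* = CTL
TH1* = TH1
TH2* = TH2
APC* = APC

# --- cytokines and soluble mediators ---
IL12* = DC or MAC
TNFA* = MAC or TH1
IL6* = DC or MAC or TH2
TGFB* = TREG
IL10* = TREG or TH2 or DC
IFNG* = TH1 or CTL
IL4* = TH2

# --- receptors / proximal transducers ---
TNFR* = TNFA
GP130* = IL6
FASL* = CTL
FAS* = FASL
SMAD* = TGFB

# --- JAK/STAT with SOCS negative feedback ---
JAK* = GP130 and not SOCS
STAT3* = JAK
SOCS* = STAT3

# --- NF-kB module (IKK needs inflammatory co-signal) ---
IKK* = TNFR or (AKT and STAT3)
IKB* = not IKK
NFKB* = not IKB

# --- COX2 / PGE2 axis ---
COX2* = NFKB or STAT3
PGE2* = COX2
EP2* = PGE2

# --- ERK MAPK cascade ---
RAS* = GP130 or EP2
RAF* = RAS
MEK* = RAF
ERK* = MEK
FOS* = ERK
JUN* = ERK

# --- PI3K/AKT ---
PI3K* = (TNFR or EP2 or GP130) and not PTEN
AKT* = PI3K and not PP2A
PTEN* = P53
GSK3B* = not AKT
MTOR* = AKT

# --- oxidative stress and the P53 axis ---
ROS* = TNFR or COX2
ATM* = ROS
P53* = (ATM or P53) and not MDM2
MDM2* = (P53 or AKT) and not GSK3B
P21* = P53 or SMAD
CYCLIND1* = (BCATENIN or STAT3) and not GSK3B
BCATENIN* = not (APC and GSK3B)

# --- sphingolipid rheostat ---
SPHK1* = TNFR or GP130
S1P* = SPHK1
CERAMIDE* = (TNFR or ROS) and not SPHK1

# --- mitochondrial apoptosis ---
PP2A* = CERAMIDE and not MTOR
BCL2* = (AKT or NFKB) and not PP2A
BAX* = P53 and not BCL2
CASP8* = FAS
TBID* = CASP8
MOMP* = (BAX or TBID or CERAMIDE) and not BCL2
CYTC* = MOMP
IAP* = NFKB and not MOMP
CASP9* = CYTC and not IAP
CASP3* = (CASP9 or CASP8) and not IAP

# --- outputs ---
Proliferation* = CYCLIND1 and not P21
Apoptosis* = CASP3
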