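# Transient dendritic-cell activation: DC starts ON but is free to evolve
# (it deactivates once IL10 tone builds up); other immune cells clamped OFF;
# cytokines start OFF so the inflammatory pulse is DC-driven.
default_initial = uniform_random

[fixed]
MAC = OFF
TREG = OFF
CTL = OFF
TH1 = OFF
TH2 = OFF
APC = ON

[initial]
DC = ON
IL12 = OFF
TNFA = OFF
IL6 = OFF
TGFB = OFF
IL10 = OFF
IFNG = OFF
IL4 = OFF
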