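# Pro-tumour inflammatory microenvironment: dendritic cells permanently
# activated (DC clamped ON), all other immune cells absent, APC expressed.
default_initial = uniform_random

[fixed]
DC = ON
MAC = OFF
TREG = OFF
CTL = OFF
TH1 = OFF
TH2 = OFF
APC = ON
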