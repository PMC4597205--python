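# Non-inflammatory microenvironment: every immune cell absent (clamped OFF),
# APC constitutively expressed (clamped ON); intracellular nodes start random.
default_initial = uniform_random

[fixed]
DC = OFF
MAC = OFF
TREG = OFF
CTL = OFF
TH1 = OFF
TH2 = OFF
APC = ON
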