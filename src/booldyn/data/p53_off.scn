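# Transformed cell in a pro-tumour microenvironment: DC clamped ON and P53
# clamped OFF (inactivating mutation) simultaneously.
default_initial = uniform_random

[fixed]
DC = ON
MAC = OFF
TREG = OFF
CTL = OFF
TH1 = OFF
TH2 = OFF
APC = ON
P53 = OFF
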