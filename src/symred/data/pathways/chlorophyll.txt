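# Chlorophyll a biosynthesis from protoporphyrin IX.
# ChlLNB (light-independent protochlorophyllide reductase) marks
# capability beyond the reference; POR is the light-dependent slot.
@pathway chlorophyll
@supplement chlL, chlN, chlB
chlH: chlH
chlM: chlM
acsF: acsF
por: por
chlG: chlG
chlP: chlP
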