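# Tricarboxylic acid cycle (cyanobacterial variant: the 2-oxoglutarate
# dehydrogenase step is substituted by the OGDC/SSADH shunt).
@pathway tca
gltA: gltA
acnB: acnB
icd: icd
ogdc: ogdcA, ogdcB
ssadh: gabD
sdh: sdhA, sdhB
fumC: fumC
mdh: mdh
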