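# Folate (tetrahydrofolate) biosynthesis from GTP.
@pathway folate
folE: folE
folB: folB
folK: folK
folP: folP
folC: folC
folA: folA, folM
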