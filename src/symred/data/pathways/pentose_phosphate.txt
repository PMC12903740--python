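# Oxidative and non-oxidative pentose phosphate pathway.
@pathway pentose_phosphate
zwf: zwf
pgl: pgl
gnd: gnd
rpe: rpe
rpi: rpiA
tkt: tktA
tal: talB | bypass: tkt, rpe
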