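# Entner-Doudoroff route, glucose-6-P -> pyruvate + glyceraldehyde-3-P.
# The lower half can be bypassed by a complete EMP lower branch.
@pathway entner_doudoroff
zwf: zwf
pgl: pgl
edd: edd
eda: eda
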