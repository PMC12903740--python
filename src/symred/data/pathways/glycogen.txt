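# Glycogen synthesis and mobilization.
@pathway glycogen
glgC: glgC
glgA: glgA
glgB: glgB
glgP: glgP, glgX
malQ: malQ
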