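# Pseudocobalamin biosynthesis (corrin ring assembly, abridged).
@pathway pseudocobalamin
cobA: cobA
cbiL: cbiL
cbiH: cbiH
cbiF: cbiF
cbiC: cbiC
cbiA: cbiA
cobU: cobU
cobS: cobS
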