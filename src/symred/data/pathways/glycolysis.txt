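# Glycolysis (Embden-Meyerhof-Parnas), glucose-6-P -> pyruvate.
# GapN (non-phosphorylating NADP-dependent GAPDH) marks a reductant-
# generating capability beyond the free-living reference.
@pathway glycolysis
@supplement gapN
pgi: pgi
pfk: pfkA, pfkB
fba: fbaA, fbaB
tpi: tpiA
gap: gap1, gap2
pgk: pgk
gpm: gpmA, gpmB
eno: eno
pyk: pykA, pykF
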