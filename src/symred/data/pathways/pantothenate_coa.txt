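# Pantothenate and coenzyme A biosynthesis.
@pathway pantothenate_coa
panB: panB
panC: panC
coaA: coaA
coaBC: coaBC
coaD: coaD
coaE: coaE
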