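# Biotin biosynthesis from pimeloyl-ACP.
@pathway biotin
bioF: bioF
bioA: bioA
bioD: bioD
bioB: bioB
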