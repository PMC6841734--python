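>hsa-miR-199b-5p gene=MIR199B
CCCAGUGUUUAGACUAUCUGUUC
>hsa-miR-199a-5p gene=MIR199A1
CCCAGUGUUCAGACUACCUGUUC
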