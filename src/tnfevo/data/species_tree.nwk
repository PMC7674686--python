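(((Petromyzon_marinus:1.0,Lethenteron_camtschaticum:1.0)lamprey_ancestor:1.0,Eptatretus_burgeri:2.0)agnathan_ancestor:1.0,((Rhincodon_typus:2.0,Callorhinchus_milii:2.0)chondrichthyan_ancestor:1.0,(((Danio_rerio:1.0,Takifugu_rubripes:1.0)teleost_ancestor:1.0,Lepisosteus_oculatus:2.0)actinopterygian_ancestor:0.5,(Latimeria_chalumnae:2.0,Homo_sapiens:2.0)sarcopterygian_ancestor:0.5)osteichthyan_ancestor:0.5)gnathostome_ancestor:1.0)vertebrate_ancestor;
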