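type,g0,g1,g2,g3,g4
renal,0.0,0.5,0.75,1.0,1.5
hematological,0.0,0.5,0.75,1.0,1.5
neurological,0.0,0.25,0.5,0.75,1.0
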