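shell,binding_keV,jump_ratio
K,80.7249,4.2
L1,14.3528,1.14
L2,13.7336,1.41
L3,11.9187,2.5
M,2.58,2.0
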