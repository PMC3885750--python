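congener,tef
Nap,0.001
Acy,0.001
Ace,0.001
Fluo,0.001
Phe,0.001
Ant,0.01
Flu,0.001
Pyr,0.001
Chry,0.01
BaA,0.1
BbF,0.1
BkF,0.1
BaP,1.0
DBA,1.0
IP,0.1
BghiP,0.01
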