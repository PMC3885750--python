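congener,particle_fraction
Nap,0.05
Acy,0.05
Ace,0.05
Fluo,0.05
Phe,0.05
Ant,0.05
Flu,0.05
Pyr,0.05
Chry,0.5
BaA,0.5
BbF,1.0
BkF,1.0
BaP,1.0
DBA,1.0
IP,1.0
BghiP,1.0
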