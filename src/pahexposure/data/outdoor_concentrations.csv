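congener,season,median_ng_m3,sd_ng_m3
Nap,spring,1674.7,3632.8
Acy,spring,1076.3,2447.8
Ace,spring,78.9,101.6
Fluo,spring,122.3,239.6
Phe,spring,157.5,393.9
Ant,spring,11.3,29.0
Flu,spring,79.6,173.4
Pyr,spring,23.2,38.0
Chry,spring,8.8,14.5
BaA,spring,8.6,11.4
BbF,spring,6.9,14.8
BkF,spring,5.5,26.1
BaP,spring,7.6,14.9
DBA,spring,1.8,3.3
IP,spring,4.5,7.7
BghiP,spring,4.7,9.0
Nap,summer,3961.6,12071.8
Acy,summer,695.0,1384.5
Ace,summer,22.0,21.4
Fluo,summer,69.8,119.5
Phe,summer,96.1,219.1
Ant,summer,6.6,17.7
Flu,summer,46.8,103.8
Pyr,summer,9.3,15.5
Chry,summer,7.2,12.8
BaA,summer,1.3,2.1
BbF,summer,3.2,7.7
BkF,summer,1.3,6.8
BaP,summer,1.3,2.1
DBA,summer,1.3,2.6
IP,summer,2.4,4.3
BghiP,summer,1.8,3.7
Nap,autumn,3532.0,8626.9
Acy,autumn,780.3,2215.0
Ace,autumn,75.6,93.1
Fluo,autumn,126.7,253.0
Phe,autumn,104.9,262.0
Ant,autumn,12.8,37.5
Flu,autumn,59.7,133.6
Pyr,autumn,14.5,22.9
Chry,autumn,8.1,14.8
BaA,autumn,2.8,4.0
BbF,autumn,7.2,17.7
BkF,autumn,2.1,9.3
BaP,autumn,3.1,5.0
DBA,autumn,1.8,3.7
IP,autumn,4.7,8.1
BghiP,autumn,6.1,11.1
Nap,winter,1699.3,4071.3
Acy,winter,1638.1,3725.2
Ace,winter,141.4,149.8
Fluo,winter,177.1,339.7
Phe,winter,331.0,840.6
Ant,winter,43.0,115.3
Flu,winter,219.6,552.6
Pyr,winter,62.2,108.4
Chry,winter,24.0,44.3
BaA,winter,19.1,27.7
BbF,winter,24.3,55.2
BkF,winter,10.5,48.6
BaP,winter,13.4,21.9
DBA,winter,3.9,7.3
IP,winter,9.8,18.6
BghiP,winter,13.9,22.6
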