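source,congener,phase,ng_per_unit
cigarette,Nap,particle,150.0
cigarette,Nap,gas,2850.0
cigarette,Acy,particle,10.0
cigarette,Acy,gas,190.0
cigarette,Ace,particle,7.5
cigarette,Ace,gas,142.5
cigarette,Fluo,particle,20.0
cigarette,Fluo,gas,380.0
cigarette,Phe,particle,30.0
cigarette,Phe,gas,570.0
cigarette,Ant,particle,7.5
cigarette,Ant,gas,142.5
cigarette,Flu,particle,15.0
cigarette,Flu,gas,285.0
cigarette,Pyr,particle,12.5
cigarette,Pyr,gas,237.5
cigarette,Chry,particle,50.0
cigarette,Chry,gas,50.0
cigarette,BaA,particle,40.0
cigarette,BaA,gas,40.0
cigarette,BbF,particle,50.0
cigarette,BbF,gas,0.0
cigarette,BkF,particle,30.0
cigarette,BkF,gas,0.0
cigarette,BaP,particle,60.0
cigarette,BaP,gas,0.0
cigarette,DBA,particle,10.0
cigarette,DBA,gas,0.0
cigarette,IP,particle,40.0
cigarette,IP,gas,0.0
cigarette,BghiP,particle,50.0
cigarette,BghiP,gas,0.0
wood_crop,Nap,particle,7500.0
wood_crop,Nap,gas,142500.0
wood_crop,Acy,particle,750.0
wood_crop,Acy,gas,14250.0
wood_crop,Ace,particle,375.0
wood_crop,Ace,gas,7125.0
wood_crop,Fluo,particle,750.0
wood_crop,Fluo,gas,14250.0
wood_crop,Phe,particle,2000.0
wood_crop,Phe,gas,38000.0
wood_crop,Ant,particle,375.0
wood_crop,Ant,gas,7125.0
wood_crop,Flu,particle,1000.0
wood_crop,Flu,gas,19000.0
wood_crop,Pyr,particle,750.0
wood_crop,Pyr,gas,14250.0
wood_crop,Chry,particle,3000.0
wood_crop,Chry,gas,3000.0
wood_crop,BaA,particle,1750.0
wood_crop,BaA,gas,1750.0
wood_crop,BbF,particle,3000.0
wood_crop,BbF,gas,0.0
wood_crop,BkF,particle,1500.0
wood_crop,BkF,gas,0.0
wood_crop,BaP,particle,1000.0
wood_crop,BaP,gas,0.0
wood_crop,DBA,particle,100.0
wood_crop,DBA,gas,0.0
wood_crop,IP,particle,1750.0
wood_crop,IP,gas,0.0
wood_crop,BghiP,particle,2500.0
wood_crop,BghiP,gas,0.0
lpg,Nap,particle,2500.0
lpg,Nap,gas,47500.0
lpg,Acy,particle,250.0
lpg,Acy,gas,4750.0
lpg,Ace,particle,100.0
lpg,Ace,gas,1900.0
lpg,Fluo,particle,150.0
lpg,Fluo,gas,2850.0
lpg,Phe,particle,400.0
lpg,Phe,gas,7600.0
lpg,Ant,particle,50.0
lpg,Ant,gas,950.0
lpg,Flu,particle,150.0
lpg,Flu,gas,2850.0
lpg,Pyr,particle,100.0
lpg,Pyr,gas,1900.0
lpg,Chry,particle,250.0
lpg,Chry,gas,250.0
lpg,BaA,particle,150.0
lpg,BaA,gas,150.0
lpg,BbF,particle,200.0
lpg,BbF,gas,0.0
lpg,BkF,particle,100.0
lpg,BkF,gas,0.0
lpg,BaP,particle,50.0
lpg,BaP,gas,0.0
lpg,DBA,particle,5.0
lpg,DBA,gas,0.0
lpg,IP,particle,80.0
lpg,IP,gas,0.0
lpg,BghiP,particle,100.0
lpg,BghiP,gas,0.0
coal,Nap,particle,18000.0
coal,Nap,gas,342000.0
coal,Acy,particle,1800.0
coal,Acy,gas,34200.0
coal,Ace,particle,900.0
coal,Ace,gas,17100.0
coal,Fluo,particle,1800.0
coal,Fluo,gas,34200.0
coal,Phe,particle,4800.0
coal,Phe,gas,91200.0
coal,Ant,particle,900.0
coal,Ant,gas,17100.0
coal,Flu,particle,2400.0
coal,Flu,gas,45600.0
coal,Pyr,particle,1800.0
coal,Pyr,gas,34200.0
coal,Chry,particle,7200.0
coal,Chry,gas,7200.0
coal,BaA,particle,4200.0
coal,BaA,gas,4200.0
coal,BbF,particle,7200.0
coal,BbF,gas,0.0
coal,BkF,particle,3600.0
coal,BkF,gas,0.0
coal,BaP,particle,2400.0
coal,BaP,gas,0.0
coal,DBA,particle,240.0
coal,DBA,gas,0.0
coal,IP,particle,4200.0
coal,IP,gas,0.0
coal,BghiP,particle,6000.0
coal,BghiP,gas,0.0
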