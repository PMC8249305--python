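locus,locus_type,linkage_group,source_species,annealing_temp_C,size_min_bp,size_max_bp,size_approximate,n_alleles,n_unique_alleles,n_genotypes,pic
BPPCT007,SSR,G3,peach,57,122,154,False,17,5,16,0.91
BPPCT025,SSR,G6,peach,57,132,208,False,24,7,16,0.94
BPPCT037,SSR,G5,peach,57,100,120,False,5,2,6,0.54
BPPCT038,SSR,G5,peach,57,110,140,False,6,0,8,0.77
BPPCT039,SSR,G3,peach,57,122,146,False,7,0,11,0.76
BPPCT040,SSR,G4,peach,57,120,154,False,12,1,15,0.89
CPDCT044,SSR,G2,almond,58,162,252,False,24,11,16,0.94
CPSCT021,SSR,G2,plum,56,124,208,False,26,9,16,0.95
EPDCU5100,EST-SSR,G1,almond,57,124,144,False,8,1,11,0.83
PaConsII,S-RNase,G6,sweet cherry,58,490,3000,True,23,6,16,0.93
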