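allele,size_bp,approximate,sequenced,reported_frequency_pct,occ_spinosa,occ_insititia,occ_hybrid,occ_total
S_3-1,713,False,True,6.33,2,2,1,5
S_12,815,False,True,7.59,3,2,1,6
S_A,627,False,True,2.53,1,1,0,2
S_B,559,False,True,7.59,3,1,2,6
S_C,783,False,True,11.39,4,3,2,9
S_D,716,False,True,3.80,1,2,0,3
S_E,2100,True,False,1.27,1,0,0,1
S_G,980,True,False,1.27,0,1,0,1
S_H,1250,True,False,3.80,2,0,1,3
S_I,950,True,False,2.53,1,1,0,2
S_J,1013,False,True,2.53,1,1,0,2
S_K,1450,True,True,5.06,2,1,1,4
S_L,3000,True,False,2.53,1,1,0,2
S_M,1113,False,True,6.33,3,0,2,5
S_N,2500,True,False,1.27,1,0,0,1
S_O,490,True,False,1.27,1,0,0,1
S_P,1800,True,True,5.06,3,0,1,4
S_Q,610,True,False,1.27,1,0,0,1
S_T,2700,True,False,1.27,0,0,1,1
S_U,1400,True,True,3.80,1,2,0,3
S_V,1500,True,False,2.53,2,0,0,2
S_X,2600,True,False,2.53,1,0,1,2
S_Y,590,True,False,2.53,0,2,0,2
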