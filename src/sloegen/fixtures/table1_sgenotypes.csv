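accession,species,ploidy,origin,alleles
A1,P_insititia,6,"Apagy, SSB, HUN",S_A;S_B;S_G;S_U
B3,P_insititia,6,"Berkesz, SSB, HUN",S_C;S_I;S_J;S_K;S_L
D2,P_spinosa,4,"Szeghalom, BEK, HUN",S_3-1;S_B;S_I;S_M
D4,P_spinosa,4,"Mezobereny, BEK, HUN",S_12;S_C;S_K;S_N
D5,P_spinosa,4,"Mezobereny, BEK, HUN",S_3-1;S_M;S_O;S_P
L1,hybrid,5,"Lovopetri, SSB, HUN",S_3-1;S_B;S_C;S_M
L2,hybrid,5,"Lovopetri, SSB, HUN",S_12;S_B;S_C;S_K;S_T
L4/1,hybrid,5,"Lovopetri, SSB, HUN",S_H;S_M;S_P;S_X
S3,P_spinosa,4,"Sarospatak, SSB, HUN",S_C;S_P
L5,P_spinosa,4,"Lovopetri, SSB, HUN",S_12;S_B;S_H;S_M
S3/B,P_spinosa,4,"Sarospatak, SSB, HUN",S_H;S_K
U1,P_spinosa,4,"Ujkenez, SSB, HUN",S_A;S_P;S_X;S_V
T1,P_insititia,6,"Mezoladany, BAZ, HUN",S_3-1;S_12;S_C;S_D;S_U;S_Y
T4,P_insititia,6,"Mezoladany, BAZ, HUN",S_3-1;S_12;S_C;S_D;S_U;S_Y
ZE,P_spinosa,4,"Nagykapos, NAM, SLO",S_12;S_C;S_J;S_Q
Z3,P_spinosa,4,"Pacin, BAZ, HUN",S_B;S_D;S_E;S_V
S2,P_spinosa,4,"Sarospatak, SSB, HUN",S_C;S_L
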