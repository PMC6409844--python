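site,compartment,element,se_mg_per_g
Site I,soil,Al,32.90069
Site I,soil,Be,0.07197
Site I,soil,Ba,1.08289
Site I,soil,Ca,101.56333
Site I,soil,Cd,0.2784
Site I,soil,Co,0.01354
Site I,soil,Cr,0.29671
Site I,soil,Cu,0.84077
Site I,soil,Fe,6.97426
Site I,soil,Mg,8.54049
Site I,soil,Mn,1.15156
Site I,soil,Mo,0.01091
Site I,soil,Ni,0.07573
Site I,soil,Pb,0.07672
Site I,soil,V,0.07972
Site I,soil,Zn,7.21991
Site II,soil,Al,57.72633
Site II,soil,Be,0.11393
Site II,soil,Ba,1.45522
Site II,soil,Ca,88.38769
Site II,soil,Cd,0.2207
Site II,soil,Co,0.00968
Site II,soil,Cr,0.09240
Site II,soil,Cu,0.61136
Site II,soil,Fe,8.31177
Site II,soil,Mg,6.22629
Site II,soil,Mn,1.31417
Site II,soil,Mo,0.01586
Site II,soil,Ni,0.04804
Site II,soil,Pb,0.07582
Site II,soil,V,0.11612
Site II,soil,Zn,9.78533
Site I,biota,Al,75.84870
Site I,biota,Be,3.09869
Site I,biota,Ba,1.92336
Site I,biota,Ca,2672.88999
Site I,biota,Cd,0.10056
Site I,biota,Co,0.09498
Site I,biota,Cr,0.58658
Site I,biota,Cu,14.69708
Site I,biota,Fe,138.77551
Site I,biota,Mg,523.75384
Site I,biota,Mn,3.97113
Site I,biota,Mo,0.18244
Site I,biota,Ni,0.41954
Site I,biota,Pb,0.78007
Site I,biota,V,0.42388
Site I,biota,Zn,31.53582
Site II,biota,Al,406.63030
Site II,biota,Be,1.88832
Site II,biota,Ba,2.59292
Site II,biota,Ca,1277.84243
Site II,biota,Cd,0.09159
Site II,biota,Co,0.18576
Site II,biota,Cr,0.94224
Site II,biota,Cu,5.94914
Site II,biota,Fe,250.35349
Site II,biota,Mg,428.84791
Site II,biota,Mn,2.76065
Site II,biota,Mo,0.13122
Site II,biota,Ni,0.57519
Site II,biota,Pb,0.66487
Site II,biota,V,0.59009
Site II,biota,Zn,48.74656
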