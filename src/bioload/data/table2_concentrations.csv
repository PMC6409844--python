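site,compartment,element,replicate,value_mg_per_g
Site I,soil,Al,1,196.0533
Site I,soil,Be,1,0.4422
Site I,soil,Ba,1,2.4420
Site I,soil,Ca,1,883.5467
Site I,soil,Cd,1,0.1060
Site I,soil,Co,1,0.519
Site I,soil,Cr,1,0.6619
Site I,soil,Cu,1,3.0313
Site I,soil,Fe,1,26.2683
Site I,soil,Mg,1,65.3030
Site I,soil,Mn,1,2.8454
Site I,soil,Mo,1,0.0383
Site I,soil,Ni,1,0.2883
Site I,soil,Pb,1,0.1553
Site I,soil,V,1,0.2692
Site I,soil,Zn,1,42.4307
Site II,soil,Al,1,378.4967
Site II,soil,Be,1,0.3940
Site II,soil,Ba,1,4.1214
Site II,soil,Ca,1,455.5233
Site II,soil,Cd,1,0.0847
Site II,soil,Co,1,0.0264
Site II,soil,Cr,1,0.2162
Site II,soil,Cu,1,2.8978
Site II,soil,Fe,1,32.3260
Site II,soil,Mg,1,26.6207
Site II,soil,Mn,1,6.3062
Site II,soil,Mo,1,0.475
Site II,soil,Ni,1,0.1363
Site II,soil,Pb,1,0.2074
Site II,soil,V,1,0.3537
Site II,soil,Zn,1,89.7970
Site I,biota,Al,1,961.9387
Site I,biota,Be,1,12.1700
Site I,biota,Ba,1,6.8607
Site I,biota,Ca,1,9625.6327
Site I,biota,Cd,1,0.4533
Site I,biota,Co,1,0.2793
Site I,biota,Cr,1,2.1513
Site I,biota,Cu,1,42.7720
Site I,biota,Fe,1,441.7793
Site I,biota,Mg,1,2009.0593
Site I,biota,Mn,1,14.6213
Site I,biota,Mo,1,0.4327
Site I,biota,Ni,1,1.5987
Site I,biota,Pb,1,3.0707
Site I,biota,V,1,1.6913
Site I,biota,Zn,1,124.9000
Site II,biota,Al,1,1514.1020
Site II,biota,Be,1,6.3833
Site II,biota,Ba,1,8.9527
Site II,biota,Ca,1,4835.3907
Site II,biota,Cd,1,0.3529
Site II,biota,Co,1,0.4573
Site II,biota,Cr,1,2.8853
Site II,biota,Cu,1,23.2357
Site II,biota,Fe,1,940.9813
Site II,biota,Mg,1,1656.1273
Site II,biota,Mn,1,11.5678
Site II,biota,Mo,1,0.4313
Site II,biota,Ni,1,2.0727
Site II,biota,Pb,1,2.6593
Site II,biota,V,1,2.2733
Site II,biota,Zn,1,185.1847
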