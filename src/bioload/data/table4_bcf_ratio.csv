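element,bcf_site1,bcf_site2,ratio_site1_site2
Al,5.1183,3.4995,0.5222
Be,28.290,19.088,1.9065
Ba,3.3319,2.5774,0.7663
Ca,10.611,8.9935,1.9906
Cd,2.7169,2.5480,1.2519
Co,6.4979,26.032,0.5249
Cr,2.5215,18.137,0.7456
Cu,22.586,7.3969,1.8408
Fe,17.825,27.608,0.5694
Mg,27.394,50.377,1.2131
Mn,4.5726,3.0160,0.6498
Mo,15.919,11.677,1.4667
Ni,5.9092,19.347,0.7713
Pb,19.774,11.263,1.1546
V,4.6089,6.1567,0.7439
Zn,2.0687,1.6891,0.6744
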