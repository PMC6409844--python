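element,cf_site1,cf_site2,pli_site1,pli_site2,dc_site1,dc_site2
Al,1633.7,3154.1,0.7648,1.0632,4876.3,9765.2
Be,2.2113,1.9701,0.2778,0.3923,6.2453,5.7873
Ba,15.262,25.758,0.8440,0.1756,45.785,76.256
Ca,883.35,455.52,0.4402,0.3170,2576.2,1298.6
Cd,2.6501,2.1175,0.1610,0.3159,7.9343,6.0549
Co,25.951,1.3242,0.1717,1.2919,75.987,3.6757
Cr,16.547,5.4052,0.6619,0.1899,43.765,13.657
Cu,60.626,57.956,0.1346,0.1541,175.76,169.65
Fe,2626.8,3232.6,1.6551,8.8810,7545.6,9654.7
Mg,6530.3,2662.1,1.0747,1.5895,18545.2,7644.5
Mn,56.908,126.12,0.1628,0.1495,165.87,325.54
Mo,4.7661,9.5202,0.0277,0.0347,2.0857,26.549
Ni,288.32,136.30,0.1252,0.1183,765.98,389.98
Pb,1.1946,1.5953,1.7578,0.7389,3.4598,4.2983
V,5.3842,7.0743,0.0192,0.0847,15.986,20.765
Zn,1060.7,2244.9,1.2509,2.6525,3058.4,6375.6
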