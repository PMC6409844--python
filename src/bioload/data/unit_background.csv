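element,background_mg_per_g
Al,1.0
Be,1.0
Ba,1.0
Ca,1.0
Cd,1.0
Co,1.0
Cr,1.0
Cu,1.0
Fe,1.0
Mg,1.0
Mn,1.0
Mo,1.0
Ni,1.0
Pb,1.0
V,1.0
Zn,1.0
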