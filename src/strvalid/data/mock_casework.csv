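sample,gf_alleles_called,idp_alleles_called
Soda Can Swab 1,40,26
Soda Can Swab 2,40,26
Soda Can Swab 3,40,26
Cig Butt 1,18,11
Cig Butt 2,40,28
Cig Butt 3,40,28
Blood on Soil Day0,40,27
Blood on Soil Day1,40,27
Blood on Soil Day2,24,18
Blood on Soil Day3,0,0
Blood on Wood,41,27
Blood on Metal,41,27
Blood on Metal (Flocked Swab),41,27
Semen on Cloth,41,27
Semen on Cloth with UV,41,27
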