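sample_id,locus,allele1,allele2
CTRL-M-SYN,D3S1358,15,16
CTRL-M-SYN,vWA,14,16
CTRL-M-SYN,D16S539,9,10
CTRL-M-SYN,CSF1PO,11,12
CTRL-M-SYN,TPOX,8,8
CTRL-M-SYN,AMEL,X,Y
CTRL-M-SYN,DYS391,11,
CTRL-M-SYN,D8S1179,12,13
CTRL-M-SYN,D21S11,28,31
CTRL-M-SYN,D18S51,12,15
CTRL-M-SYN,Yindel,2,
CTRL-M-SYN,D2S441,14,15
CTRL-M-SYN,D19S433,14,15
CTRL-M-SYN,TH01,7,9.3
CTRL-M-SYN,FGA,24,26
CTRL-M-SYN,D22S1045,11,16
CTRL-M-SYN,D5S818,11,11
CTRL-M-SYN,D13S317,11,11
CTRL-M-SYN,D7S820,7,12
CTRL-M-SYN,SE33,17,25.2
CTRL-M-SYN,D10S1248,12,15
CTRL-M-SYN,D1S1656,13,16
CTRL-M-SYN,D12S391,18,19
CTRL-M-SYN,D2S1338,20,23
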