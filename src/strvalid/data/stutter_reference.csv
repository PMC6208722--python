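locus,position,n_obs,mean_pct,min_pct,max_pct,sd_pct,printed_mean_plus_3sd_pct
CSF1PO,minus_repeat,1359,5.22,1.82,10.25,1.1852,8.77
D10S1248,minus_repeat,1512,7.07,2.13,12.58,1.4631,11.46
D12S391,minus_repeat,1696,7.50,2.11,15.51,2.0544,13.66
D13S317,minus_repeat,1275,4.87,1.49,14.51,1.4412,9.19
D16S539,minus_repeat,1400,5.16,2.05,9.76,1.4379,9.48
D18S51,minus_repeat,1745,6.94,2.68,15.8,1.8249,12.42
D19S433,minus_repeat,1591,6.10,2.36,10.94,1.2924,9.97
D1S1656,minus_repeat,1744,7.14,2.9,15,1.6897,12.21
D1S1656,minus_2nt,242,1.56,0.66,3.38,0.2972,2.45
D21S11,minus_repeat,1652,6.69,2.52,13.95,1.2514,10.45
D22S1045,minus_repeat,1372,7.69,1.31,21.46,2.8559,16.26
D22S1045,plus_repeat,1002,4.26,0.85,7.34,0.8103,6.69
D2S1338,minus_repeat,1861,7.10,2.41,13.79,1.5435,11.73
D2S441,minus_repeat,1397,4.54,1.3,12.18,1.1852,8.10
D3S1358,minus_repeat,1481,7.18,2.74,14.5,1.2669,10.98
D5S818,minus_repeat,1354,5.54,1.8,9.85,1.2056,9.16
D7S820,minus_repeat,1275,4.41,1.44,11.46,1.3023,8.32
D8S1179,minus_repeat,1566,5.84,1.96,12.99,1.2519,9.60
DYS391,minus_repeat,606,5.17,3.45,8.05,0.7557,7.43
FGA,minus_repeat,1691,6.84,2.96,12.89,1.5692,11.55
SE33,minus_repeat,1991,8.87,3.22,16.81,1.8728,14.49
SE33,minus_2nt,1231,2.75,1.27,4.95,0.4063,3.97
TH01,minus_repeat,586,2.37,1.03,4.99,0.6946,4.45
TPOX,minus_repeat,679,2.81,1.06,10.21,0.9148,5.55
vWA,minus_repeat,1516,6.23,1.97,11.75,1.4982,10.73
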