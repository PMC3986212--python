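segment,location,available_sequences,length_bp,n_snps,n_haplotypes,hd,pi
Cs1g16760,chr1:20042999-20043567,40,569,2,4,0.57,0.0012
Cs1g23450,chr1:25990710-25991189,40,499,3,4,0.50,0.0012
Cs2g19680,chr2:16533735-16534365,40,631,2,3,0.56,0.0010
Cs2g31250,chr2:30595507-30595981,40,475,5,4,0.31,0.0028
Cs4g07130,chr4:4533481-4533998,40,518,5,5,0.69,0.0032
Cs4g15590,chr4:14833018-14833473,40,456,3,2,0.50,0.0033
Cs5g15460,chr5:13684338-13684914,40,577,3,4,0.53,0.0010
Cs7g10980,chr7:7194703-7195183,40,473,6,9,0.77,0.0049
Cs7g31800,chr7:31599722-31600139,38,454,1,2,0.19,0.0004
Cs9g04300,chr9:2379414-2379892,40,479,6,6,0.69,0.0039
Cs9g14320,chr9:13716462-13717019,38,558,10,8,0.80,0.0061
Cs9g16170,chr9:15595778-15596191,36,410,8,5,0.75,0.0060
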