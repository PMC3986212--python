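group,accession,Cs1g16760,Cs1g23450,Cs2g19680,Cs2g31250,Cs4g07130,Cs4g15590,Cs5g15460,Cs7g10980,Cs7g31800,Cs9g04300,Cs9g14320,Cs9g16170
wendan,Dayongjuhuaxin,1/2,2/5,1/1,5/5,3/5,2/2,4/7,5/10,1/1,4/5,1/2,1/2
wendan,Fujianwendan,1/2,5/5,2/4,2/4,3/3,1/2,4/6,7/9,1/1,1/2,1/6,3/4
wendan,Guanximiyou,2/2,5/5,1/1,4/5,1/2,1/2,4/6,6/6,1/3,1/2,1/1,4/4
wendan,Liangpingyou_cq,1/2,2/2,1/2,5/5,3/3,1/2,4/4,6/6,1/3,1/1,1/1,4/4
shatianyou,Dongguaquan,2/3,2/5,2/2,5/5,3/4,2/2,4/7,6/8,1/3,3/4,6/7,3/6
shatianyou,Hejiangyou,2/3,5/5,2/2,5/5,3/4,1/2,4/4,6/8,1/1,4/7,6/7,3/6
shatianyou,Hongxinshatianyou,2/2,2/5,2/4,5/5,3/4,1/1,7/7,8/10,1/1,4/7,5/5,3/4
shatianyou,Lingnanshatianyou,2/3,5/5,2/2,5/5,3/4,1/2,4/4,6/8,1/1,4/7,6/7,3/6
shatianyou,Meiweishatianyou,2/2,5/5,2/2,5/5,4/4,1/2,4/7,6/8,1/1,7/7,5/7,2/3
shatianyou,Zhaipoyou,2/3,5/5,1/2,5/5,2/3,2/2,4/7,6/8,1/1,1/7,1/6,-
other,Zuoshiyou,1/2,2/5,1/1,4/5,3/4,1/1,4/4,2/10,1/1,4/4,1/6,4/6
other,Unknown,1/2,2/5,1/2,4/5,1/2,1/1,4/5,6/10,1/1,1/2,1/9,2/4
other,Dianjianghongxinyou,1/2,2/2,1/2,5/5,1/4,1/1,7/7,4/10,-,4/4,1/6,6/6
other,Duanshiyou,2/3,5/5,1/2,5/5,1/4,1/1,4/4,6/6,1/1,4/4,4/9,3/4
other,HB,3/4,5/5,2/2,5/5,1/3,1/2,4/4,2/4,1/1,4/4,-,-
other,Humiyou,2/2,2/4,2/2,3/5,3/3,1/2,4/7,3/10,1/1,1/4,1/3,4/4
other,Qiyou,3/3,5/5,1/2,5/5,4/4,1/1,4/7,6/8,1/1,4/4,4/4,2/3
other,Shuhuayou,2/2,2/5,1/2,5/5,3/4,1/2,4/7,6/10,1/1,7/7,5/7,3/4
other,Taiguomiyou,2/3,2/3,1/1,4/5,3/4,2/2,4/4,2/10,1/1,4/4,1/7,2/3
other,Xianluodisuanyou,1/2,5/5,1/1,5/5,3/4,1/1,4/4,10/10,1/3,4/7,1/1,4/4
hybrid_or_unassigned,Boluoxiangyou,1/1,1/2,2/3,1/5,1/4,1/3,1/4,1/10,1/3,1/1,1/3,4/5
hybrid_or_unassigned,Jiaodaoyou,1/2,5/5,2/3,6/7,1/6,2/4,4/5,10/10,1/1,6/8,1/6,-
hybrid_or_unassigned,Tangyouzi,2/4,1/5,2/3,5/9,1/6,1/3,2/4,1/5,2/4,6/6,3/8,-
hybrid_or_unassigned,Iwaikan,1/3,5/5,2/3,5/8,3/6,1/3,2/3,1/6,2/4,4/4,3/3,5/5
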