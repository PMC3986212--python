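id,name,genbank,amplicon_bp,ho,he,pic,f
1,chr1_7539019A/G,GO241840,40,0.44,0.43,0.34,0.01
2,chr1_20043485A/G,EY724955,50,0.27,0.29,0.25,0.07
3,chr1_25991020A/T,EY722700,36,0.31,0.32,0.27,0.01
4,chr2_31491T/C,GO241741,42,0.36,0.45,0.35,0.20
5,chr2_16534248A/G,GO242464,42,0.43,0.46,0.35,0.08
6,chr2_30594899T/C,EY661549,46,0.30,0.34,0.28,0.10
7,chr2_30595627T/C,EY656665,61,0.25,0.30,0.25,0.16
8,chr3_10462341T/C,EY699140,35,0.19,0.37,0.30,0.49
9,chr3_25525170A/G,GO241356,45,0.13,0.16,0.15,0.18
10,chr4_4533744A/G,GE213353,41,0.40,0.49,0.37,0.18
11,chr4_14833122T/C,FC922642,44,0.18,0.17,0.16,0.04
12,chr5_2097500T/G,FC922009,37,0.43,0.49,0.37,0.14
13,chr5_12963514T/C,EY667938,51,0.38,0.36,0.29,0.05
14,chr5_13684450T/C,EY732058,43,0.17,0.19,0.17,0.07
15,chr5_15275826A/G,HS085998,47,0.42,0.45,0.35,0.07
16,chr6_16520557A/G,HS086273,42,0.41,0.49,0.37,0.16
17,chr7_7194644A/G,JZ120109,43,0.17,0.19,0.17,0.07
18,chr7_7195033T/G,GO241763,39,0.17,0.22,0.20,0.21
19,chr7_22205388T/C,HS088559,40,0.24,0.27,0.23,0.10
20,chr7_31599886T/G,GO242250,42,0.10,0.11,0.10,0.14
21,chr9_2379630T/G,HS088445,40,0.30,0.50,0.37,0.39
22,chr9_13716551T/C,EY688408,43,0.10,0.12,0.11,0.13
23,chr9_15596085A/G,JK694395,41,0.42,0.39,0.32,0.05
24,chrUn_5023005A/G,HS086380,44,0.47,0.48,0.37,0.03
25,chrUn_19904498A/G,GO241683,44,0.43,0.38,0.31,0.11
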