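serial,loop,1958,1980,1993,2009,2019
1,Phyt > Fing > LomF,0.0033,0.0025,0.0035,0.0221,0.0133
2,Phyt > Moll > Fing,0.0359,0.0154,0.0156,0.0382,0.0291
3,Phyt > Moll > LomF,0.0144,0.0084,0.0071,0.0490,0.0286
4,Phyt > Meio > Fing,0.0073,0.0066,0.0127,0.0358,0.0077
5,Phyt > Meio > LomF,0.0021,0.0026,0.0045,0.0243,0.0068
6,Phyt > Meio > SomF,0.0012,0.0014,0.0023,0.0120,0.0094
7,Phyt > Zoop > LomF,0.0052,0.0080,0.0146,0.0650,0.0873
8,Phyt > Zoop > Fing,0.0594,0.0415,0.0603,0.1022,0.0876
9,Phyt > Zoop > SomF,0.0080,0.0133,0.0073,0.0316,0.1051
10,Phyt > Zoop > FilF,0.2062,0.2246,0.2685,0.3818,0.0940
11,Phyt > Zoop > HerF,0.0314,0.0011,0,0,0.0842
12,Phyt > Zoop > Moll,0.0139,0.0214,0.0170,0.0261,0.1254
13,SubM > Fing > LomF,0.0641,0.0457,0.0582,0.0117,0.1139
14,SubM > Moll > Fing,0.2109,0.0980,0.0804,0.0480,0.1964
15,SubM > Moll > LomF,0.2253,0.1076,0.0915,0.0718,0.1429
16,SubM > Meio > Fing,0.0207,0.0219,0.0324,0.0366,0.0632
17,SubM > Meio > LomF,0.0156,0.0170,0.0278,0.0289,0.0414
18,SubM > Meio > SomF,0.0134,0.0132,0.0215,0.0180,0.0806
19,Detr > Fing > LomF,0.0553,0.0255,0.0446,0.0550,0.0765
20,Detr > Fing > Phyt,0.0488,0.0810,0.0421,0.1156,0.0399
21,Detr > Fing > SubM,0.4025,0.3613,0.3150,0.3412,0.2912
22,Detr > FilF > Phyt,0.1233,0.0942,0.0843,0.1949,0.0504
23,Detr > HerF > Phyt,0.0086,0,0,0.0154,0.0427
24,Detr > HerF > SubM,0.1380,0,0,0.2167,0.2335
25,Detr > Moll > Fing,0.3365,0.3992,0.1322,0.1493,0.2716
26,Detr > Moll > LomF,0.3272,0.1339,0.1405,0.2017,0.2833
27,Detr > Moll > Phyt,0.1061,0.1633,0.0527,0.1106,0.1451
28,Detr > Moll > SubM,0.7106,0.4905,0.3085,0.1847,0.6170
29,Detr > Meio > Fing,0.0723,0.0620,0.1207,0.1771,0.0702
30,Detr > Meio > LomF,0.0497,0.0454,0.0996,0.1266,0.0662
31,Detr > Meio > SomF,0.0330,0.0324,0.0695,0.0885,0.0817
32,Detr > Meio > Phyt,0.0684,0.0684,0.0906,0.1228,0.0370
33,Detr > Meio > SubM,0.2222,0.2222,0.2528,0.1668,0.1916
34,Detr > Zoop > LomF,0.1127,0.1300,0.2940,0.3093,0.3041
35,Detr > Zoop > SomF,0.1880,0.1231,0.1951,0.2137,0.3285
36,Detr > Zoop > Fing,0.5250,0.3566,0.5175,0.4611,0.2851
37,Detr > Zoop > FilF,0.7729,0.7295,0.6954,0.7113,0.3556
38,Detr > Zoop > HerF,0.0303,0.0104,0,0,0.2274
39,Detr > Zoop > Moll,0.3903,0.2825,0.2273,0.1946,0.7620
40,Detr > Zoop > Phyt,0.3052,0.3052,0.2909,0.4074,0.7896
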