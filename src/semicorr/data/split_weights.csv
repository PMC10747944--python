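split,token,cw,freq_active,freq_passive,freq_calibration,active
1,#,-0.0018,67,70,77,True
1,(,0.4051,1136,1122,1058,True
1,/,0.0,0,1,0,False
1,1,0.1432,1080,1066,1058,True
1,2,-0.0537,526,529,452,True
1,3,0.2177,244,262,226,True
1,4,-0.1914,112,123,108,True
1,5,0.4467,33,41,34,True
1,6,0.3766,7,15,12,True
1,7,0.0835,5,6,4,True
1,8,0.4559,2,3,3,True
1,9,0.0,0,1,1,False
1,=,0.4918,827,852,791,True
1,B,-0.4305,4,2,10,True
1,C,0.3553,1199,1177,1130,True
1,F,0.4496,104,91,118,True
1,Br,0.3882,70,56,115,True
1,I,0.3796,24,34,32,True
1,Cl,0.387,185,172,195,True
1,N,0.2175,601,597,514,True
1,O,-0.2029,1010,995,939,True
1,P,-0.1273,10,24,9,True
1,S,0.1072,139,137,140,True
1,[123I],0.0,0,1,0,False
1,\,0.0,0,1,0,False
1,[C-],0.0,0,0,1,False
1,[Ge],0.0,1,0,1,False
1,[N+],0.4829,66,76,98,True
1,[O-],-0.2889,70,76,99,True
1,[Se],0.0,0,0,1,False
1,[Si],0.4429,5,8,12,True
1,[Sn],-0.1457,3,1,1,True
1,[n+],0.1103,5,1,2,True
1,[nH],-0.2015,51,39,39,True
1,c,0.1066,921,909,940,True
1,n,-0.1502,213,214,202,True
1,o,-0.3202,21,17,23,True
1,s,-0.3532,30,26,43,True
2,#,-0.0156,69,60,80,True
2,(,-0.4088,1152,1118,1036,True
2,/,0.0,0,0,1,False
2,1,-0.4359,1107,1061,991,True
2,2,-0.4951,525,501,437,True
2,3,0.0739,254,245,227,True
2,4,0.1088,117,99,118,True
2,5,0.3121,37,33,27,True
2,6,-0.3768,9,13,6,True
2,7,0.1469,4,5,2,True
2,8,0.0,0,3,1,False
2,9,0.0,0,1,0,False
2,=,0.3761,840,837,801,True
2,B,-0.1819,6,4,7,True
2,C,0.0391,1205,1164,1112,True
2,F,0.3489,90,104,127,True
2,Br,0.4237,69,56,97,True
2,I,-0.3217,25,46,25,True
2,Cl,0.3727,183,180,184,True
2,N,-0.2051,619,569,521,True
2,O,-0.3873,1012,997,941,True
2,P,-0.2234,12,19,6,True
2,S,0.4145,157,125,123,True
2,[123I],0.0,0,0,1,False
2,[18F],0.0,0,0,1,False
2,\,0.0,0,0,1,False
2,[C-],0.0,0,1,0,False
2,[Ge],0.0,0,0,2,False
2,[N+],-0.111,82,81,75,True
2,[O-],0.3385,82,84,78,True
2,[Si],0.2676,8,9,15,True
2,[Sn],0.0,1,2,0,False
2,[n+],0.0,0,5,4,False
2,[nH],-0.046,41,39,40,True
2,c,-0.4981,953,895,868,True
2,n,0.1179,220,191,176,True
2,o,0.243,21,25,15,True
2,s,0.1486,36,23,31,True
3,#,0.2631,67,60,77,True
3,(,-0.3882,1109,1092,1105,True
3,/,0.0,1,0,2,False
3,1,-0.4166,1072,1048,1042,True
3,2,-0.289,511,509,471,True
3,3,0.1485,245,254,252,True
3,4,0.1888,115,118,117,True
3,5,-0.3245,35,35,38,True
3,6,0.3899,13,14,10,True
3,7,0.3989,6,6,7,True
3,8,0.0,1,4,4,False
3,9,0.0,1,3,0,False
3,=,-0.3768,838,825,824,True
3,B,0.1439,4,2,7,True
3,C,-0.4266,1179,1140,1145,True
3,F,-0.1818,98,104,113,True
3,Br,0.1097,68,58,96,True
3,I,-0.4305,30,33,34,True
3,Cl,-0.0516,180,185,189,True
3,N,0.3385,605,544,545,True
3,O,-0.0065,988,979,975,True
3,P,-0.323,13,16,11,True
3,S,0.3219,141,131,126,True
3,[123I],0.0,0,1,0,False
3,[18F],0.0,0,1,0,False
3,\,0.0,1,0,2,False
3,[Ge],0.0,1,0,1,False
3,[N+],0.1284,76,75,82,True
3,[O-],-0.4385,78,76,84,True
3,[Si],0.4327,13,7,14,True
3,[Sn],0.0,1,2,3,False
3,[V],0.0,1,0,0,False
3,[n+],-0.0209,2,1,3,True
3,[nH],-0.1779,34,44,44,True
3,c,0.4635,918,881,932,True
3,n,-0.2132,210,198,200,True
3,o,-0.3341,29,22,17,True
3,s,-0.4718,35,29,39,True
4,#,0.293,58,59,81,True
4,(,-0.4336,1157,1151,1068,True
4,/,0.0,0,1,0,False
4,1,0.1723,1102,1128,991,True
4,2,-0.3311,566,559,421,True
4,3,0.0101,286,258,214,True
4,4,-0.1253,132,114,103,True
4,5,0.092,41,38,27,True
4,6,-0.1034,16,12,8,True
4,7,0.4945,6,7,5,True
4,8,0.0289,4,3,2,True
4,9,0.0,1,1,2,False
4,=,0.4146,879,868,789,True
4,B,-0.0762,2,2,11,True
4,C,-0.0174,1180,1212,1129,True
4,F,0.3847,88,104,124,True
4,Br,0.4093,57,60,104,True
4,I,-0.2812,28,28,31,True
4,Cl,-0.4663,191,193,187,True
4,N,0.368,650,648,467,True
4,O,0.209,1022,1043,944,True
4,P,-0.1516,19,11,13,True
4,S,0.4176,146,155,111,True
4,[123I],0.0,0,0,1,False
4,[18F],0.0,0,1,0,False
4,\,0.0,0,1,0,False
4,[C-],0.0,0,0,1,False
4,[Ge],0.0,0,1,0,False
4,[N+],0.1838,74,69,100,True
4,[O-],-0.1966,75,71,105,True
4,[Se],0.0,0,0,1,False
4,[Si],0.0827,6,8,19,True
4,[Sn],0.2362,3,1,2,True
4,[V],0.0,1,0,0,False
4,[n+],0.0,1,3,7,False
4,[nH],0.3438,42,43,37,True
4,c,0.0892,948,962,869,True
4,n,0.3388,198,207,198,True
4,o,-0.2745,27,19,8,True
4,s,-0.2667,30,36,34,True
5,#,-0.1927,58,68,90,True
5,(,0.1698,1169,1136,1036,True
5,/,0.0,1,1,0,False
5,1,-0.1953,1111,1084,1005,True
5,2,0.0434,571,555,417,True
5,3,0.4368,268,270,207,True
5,4,0.4982,123,108,117,True
5,5,0.4949,35,31,36,True
5,6,-0.2375,10,10,9,True
5,7,0.461,6,4,4,True
5,8,0.1974,3,2,3,True
5,9,0.0551,2,0,1,True
5,=,-0.2514,861,864,779,True
5,B,-0.3615,3,3,7,True
5,C,-0.0744,1223,1177,1094,True
5,F,-0.0703,92,107,110,True
5,Br,0.4524,49,67,101,True
5,I,-0.3837,32,27,25,True
5,Cl,0.1357,206,182,182,True
5,N,-0.2709,646,642,489,True
5,O,-0.0999,1038,1006,926,True
5,P,-0.3508,9,22,10,True
5,S,-0.0258,144,146,126,True
5,[123I],0.0,0,1,0,False
5,[18F],0.0,0,1,0,False
5,\,0.0,1,1,0,False
5,[C-],0.0,1,0,0,False
5,[Ge],-0.2719,2,0,0,True
5,[N+],0.1633,62,78,113,True
5,[O-],-0.4126,62,81,118,True
5,[Se],0.0,0,1,0,False
5,[Si],-0.4059,11,10,11,True
5,[Sn],0.0,1,0,4,False
5,[V],0.0,1,0,0,False
5,[n+],0.0,1,3,7,False
5,[nH],0.0709,34,34,50,True
5,c,-0.2732,942,939,891,True
5,n,-0.1253,221,239,179,True
5,o,0.0797,21,19,20,True
5,s,-0.1934,34,38,25,True
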