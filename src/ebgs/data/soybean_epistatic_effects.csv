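marker_1,marker_2,variance,effect,std_err,lod,p_value,h
M3,M39,0.5519,0.7409,0.0476,52.60,0.0000,0.0648
M1,M26,0.4070,0.6365,0.0479,38.29,0.0000,0.0469
M7,M35,0.2960,-0.5417,0.0460,30.06,0.0000,0.0324
M1,M56,0.2342,-0.4832,0.0453,24.66,0.0000,0.0286
M1,M11,0.2163,0.4633,0.0446,23.42,0.0000,0.0263
M37,M59,0.1847,0.4280,0.0414,23.23,0.0000,0.0230
M7,M50,0.2234,-0.4710,0.0456,23.11,0.0000,0.0262
M1,M8,0.1722,-0.4127,0.0412,21.78,0.0000,0.0214
M4,M55,0.2026,-0.4468,0.0454,20.99,0.0000,0.0231
M8,M65,0.1768,0.4174,0.0436,19.87,0.0000,0.0223
M4,M22,0.1574,0.3950,0.0413,19.85,0.0000,0.0194
M11,M24,0.1484,0.3826,0.0414,18.51,0.0000,0.0189
M12,M42,0.1273,-0.3549,0.0385,18.39,0.0000,0.0157
M20,M24,0.1551,-0.3913,0.0426,18.32,0.0000,0.0194
M18,M80,0.1854,-0.4284,0.0475,17.67,0.0000,0.0215
M13,M34,0.1437,0.3772,0.0422,17.34,0.0000,0.0185
M13,M68,0.1175,0.3407,0.0387,16.82,0.0000,0.0156
M3,M70,0.1521,0.3866,0.0451,15.94,0.0000,0.0183
M5,M22,0.1252,0.3515,0.0418,15.37,0.0000,0.0153
M4,M79,0.1377,0.3681,0.0445,14.82,0.0000,0.0167
M4,M36,0.1016,0.3166,0.0395,13.91,0.0000,0.0120
M1,M16,0.1602,0.3975,0.0499,13.74,0.0000,0.0192
M8,M33,0.0941,-0.3046,0.0409,12.04,0.0000,0.0121
M2,M9,0.0920,0.3002,0.0434,10.37,0.0000,0.0105
M12,M24,0.0799,0.2789,0.0413,9.91,0.0000,0.0101
M27,M36,0.0748,0.2701,0.0420,8.97,0.0000,0.0094
M1,M45,0.0741,0.2695,0.0420,8.93,0.0000,0.0090
M33,M50,0.0682,0.2575,0.0435,7.61,0.0000,0.0087
M9,M19,0.0696,-0.2599,0.0443,7.46,0.0000,0.0089
M12,M71,0.0563,0.2338,0.0404,7.28,0.0000,0.0066
M8,M56,0.0630,0.2465,0.0434,7.01,0.0000,0.0077
M11,M26,0.0696,0.2596,0.0483,6.27,0.0000,0.0077
M7,M27,0.0702,-0.2605,0.0499,5.92,0.0000,0.0081
M1,M52,0.0558,-0.2322,0.0451,5.76,0.0000,0.0061
M28,M63,0.0500,0.2187,0.0437,5.43,0.0000,0.0061
M34,M38,0.0506,0.2203,0.0449,5.22,0.0000,0.0059
M53,M79,0.0520,-0.2232,0.0461,5.08,0.0000,0.0059
M39,M45,0.0495,0.2178,0.0451,5.05,0.0000,0.0055
M9,M80,0.0380,-0.1907,0.0407,4.76,0.0000,0.0043
M1,M17,0.0446,-0.2069,0.0442,4.75,0.0000,0.0051
M25,M80,0.0367,-0.1869,0.0411,4.48,0.0000,0.0042
M15,M21,0.0408,-0.1971,0.0449,4.18,0.0000,0.0051
M1,M22,0.0417,-0.1987,0.0471,3.86,0.0000,0.0050
M2,M10,0.0288,0.1643,0.0394,3.78,0.0000,0.0032
M5,M27,0.0330,-0.1769,0.0436,3.57,0.0001,0.0040
M14,M26,0.0347,-0.1810,0.0447,3.55,0.0001,0.0040
M5,M38,0.0232,-0.1454,0.0442,2.35,0.0010,0.0025
M11,M18,0.0217,-0.1408,0.0446,2.16,0.0016,0.0025
M2,M37,0.0240,-0.1480,0.0469,2.16,0.0016,0.0024
M13,M58,0.0193,0.1321,0.0428,2.07,0.0020,0.0023
M25,M53,0.0176,-0.1259,0.0421,1.94,0.0028,0.0019
M44,M80,0.0193,0.1305,0.0474,1.65,0.0059,0.0018
M22,M27,0.0132,-0.1074,0.0404,1.53,0.0079,0.0015
M10,M22,0.0136,0.1086,0.0411,1.51,0.0083,0.0016
M22,M24,0.0098,0.0921,0.0363,1.39,0.0112,0.0011
M1,M77,0.0135,-0.1061,0.0453,1.19,0.0193,0.0013
M71,M76,0.0105,-0.0930,0.0425,1.04,0.0288,0.0010
M29,M48,0.0071,0.0738,0.0415,0.68,0.0759,0.0007
M6,M67,0.0049,-0.0604,0.0364,0.60,0.0976,0.0005
M20,M45,0.0057,0.0639,0.0401,0.55,0.1114,0.0005
M1,M6,0.0037,-0.0509,0.0344,0.48,0.1385,0.0003
M22,M66,0.0035,0.0475,0.0359,0.38,0.1858,0.0003
M19,M47,0.0029,0.0419,0.0337,0.33,0.2141,0.0002
M50,M76,0.0027,0.0396,0.0338,0.30,0.2410,0.0002
M62,M68,0.0021,-0.0338,0.0316,0.25,0.2847,0.0002
M22,M23,0.0027,0.0375,0.0359,0.24,0.2964,0.0002
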