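marker,variance,effect,std_err,lod,p_value,h
M56,1.0181,1.0016,0.1228,14.44,0.0000,0.1303
M8,0.7492,0.8581,0.1118,12.77,0.0000,0.0980
M44,0.4744,-0.6783,0.1193,7.01,0.0000,0.0562
M39,0.4328,-0.6466,0.1217,6.13,0.0000,0.0525
M12,0.3084,-0.5437,0.1134,4.98,0.0000,0.0384
M22,0.3108,0.5455,0.1143,4.94,0.0000,0.0399
M51,0.3114,0.5444,0.1228,4.26,0.0000,0.0375
M65,0.2437,0.4797,0.1163,3.69,0.0000,0.0304
M69,0.2126,-0.4477,0.1109,3.53,0.0001,0.0271
M53,0.2095,0.4439,0.1111,3.46,0.0001,0.0241
M15,0.2217,-0.4543,0.1240,2.91,0.0003,0.0270
M72,0.1711,-0.3989,0.1095,2.88,0.0003,0.0210
M26,0.1781,-0.4054,0.1167,2.62,0.0005,0.0203
M23,0.1909,-0.4192,0.1241,2.47,0.0007,0.0222
M42,0.1915,0.4188,0.1267,2.37,0.0010,0.0232
M60,0.1662,-0.3900,0.1185,2.35,0.0010,0.0191
M54,0.1506,-0.3712,0.1133,2.33,0.0011,0.0173
M25,0.1437,0.3625,0.1111,2.31,0.0011,0.0181
M10,0.1336,0.3492,0.1075,2.29,0.0012,0.0166
M36,0.1433,-0.3605,0.1150,2.13,0.0017,0.0167
M4,0.1363,0.3513,0.1138,2.07,0.0020,0.0158
M16,0.1171,-0.3233,0.1121,1.80,0.0039,0.0135
M34,0.1141,0.3187,0.1120,1.76,0.0044,0.0133
M61,0.0982,-0.2951,0.1055,1.70,0.0052,0.0118
M45,0.1027,-0.2997,0.1136,1.51,0.0083,0.0116
M5,0.0961,-0.2890,0.1121,1.44,0.0099,0.0106
M13,0.0802,-0.2619,0.1081,1.27,0.0154,0.0093
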