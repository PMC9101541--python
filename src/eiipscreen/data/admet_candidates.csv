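Compound,MW,RB,DM,MV,DHB,AHB,PSA,logP,logS,PCaco,PM,HOA,VRF,VRT,QPlogBB,CNSMPO
ZINC00756618,390.5,6,3.2,1304.9,1,4.45,31.5,5.24,−5.68,1416,8,100,1,1,0.33,3.22
ZINC20762773,390.5,6,8.1,1287.3,2.25,3.75,86.8,3.98,−4.91,348,4,95,0,0,−0.92,4.81
ZINC20501905,390.5,5,6.7,1317.7,0,6.5,46.9,3.48,−3.34,125,4,85,0,0,0.29,3.22
ZINC08764971,352.4,8,5.9,1133.5,2,4,65.4,3.74,−3.92,1475,5,100,0,0,−0.55,4.73
ZINC72324535,357.5,3,6.3,1182.2,1,3,45.3,4.82,−5.97,1440,4,100,0,1,−0.28,4.53
ZINC00526223,342.4,3,2.6,1102.3,2,4,69.6,3.99,−5.73,839,3,100,0,1,−0.75,4.41
ZINC08764993,386.8,8,8.7,1202.5,2,4,63.3,4.46,−5.39,1724,5,100,0,0,−0.39,3.94
ZINC12892770,352.4,8,5.1,1179.7,2,4,68.2,4.03,−4.73,1159,5,100,0,0,−0.69,4.58
ZINC18277049,357.4,0,6.8,1087.1,2,2.5,62.2,4.61,−5.69,1541,8,100,0,1,−0.16,4.08
ZINC19323606,357.4,0,4.7,1082.3,1,6,43.7,2.55,−2.48,175,2,82,0,0,0.84,4.14
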