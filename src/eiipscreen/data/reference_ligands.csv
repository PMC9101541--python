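name,set,gold_score,vina_dg_kcal,aqvn,eiip
Intepirdine,clinical,42.36,−5.94,2.909,0.009
Cerlapirdine,clinical,36.63,−8.13,2.88,0.000
Idalopirdine,clinical,34.59,−9.193,2.55,0.089
SGS518,clinical,33.92,−9.366,2.78,0.035
Masupirdine,clinical,35.55,−10.52,2.79,0.032
AVN-211,clinical,32.30,−5.335,3.08,0.073
ZINC00756618,candidate,43.17,−13.13,2.55,0.090
ZINC20762773,candidate,39.05,−11.57,2.55,0.090
ZINC20501905,candidate,35.01,−11.47,2.55,0.090
ZINC08764971,candidate,34.65,−9.11,2.72,0.055
ZINC72324535,candidate,34.48,−10.7,2.72,0.055
ZINC00526223,candidate,34.38,−9.135,2.99,0.009
ZINC08764993,candidate,33.48,−9.371,2.72,0.055
ZINC12892770,candidate,32.94,−8.995,2.72,0.055
ZINC18277049,candidate,32.65,−9.072,2.72,0.055
ZINC19323606,candidate,32.08,−10.04,2.72,0.055
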