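nation_id,name,group,v_rank,v,s_rank,s,e_rank,e,ac_rank,ac,v_cc_rank,v_cc,v_pg_rank,v_pg
KEN,Kenya,most,1,1.00,7,0.70,1,0.67,125,0.12,1,1.00,4,0.94
BDI,Burundi,most,2,0.93,5,0.75,6,0.42,141,0.03,2,0.95,3,0.96
ERI,Eritrea,most,3,0.91,3,0.89,15,0.39,116,0.17,4,0.88,2,1.00
SDN,Sudan (former),most,4,0.87,2,0.89,31,0.32,115,0.17,7,0.83,1,1.00
SWZ,Swaziland,most,5,0.85,11,0.64,17,0.37,144,0.01,3,0.90,10,0.86
MNG,Mongolia,most,6,0.81,1,1.00,79,0.20,100,0.26,6,0.87,7,0.89
ZMB,Zambia,most,7,0.81,22,0.57,20,0.37,143,0.01,8,0.77,6,0.90
TCD,Chad,most,8,0.79,27,0.51,10,0.41,142,0.02,13,0.71,5,0.91
NER,Niger,most,9,0.79,43,0.45,2,0.52,132,0.09,15,0.70,13,0.86
TZA,United Republic of Tanzania,most,10,0.78,21,0.58,7,0.42,122,0.13,10,0.72,12,0.86
UGA,Uganda,most,11,0.77,35,0.49,5,0.44,133,0.08,18,0.68,9,0.87
MRT,Mauritania,most,12,0.76,36,0.48,3,0.49,119,0.14,11,0.71,21,0.79
CAF,Central African Republic,most,13,0.76,17,0.61,63,0.23,147,0.00,9,0.75,8,0.89
ETH,Ethiopia,most,14,0.75,18,0.61,23,0.36,118,0.14,16,0.69,11,0.86
NAM,Namibia,most,15,0.74,8,0.66,25,0.35,111,0.21,14,0.71,16,0.82
NZL,New Zealand,least,134,0.15,45,0.44,98,0.14,5,0.83,137,0.15,132,0.19
NLD,Netherlands,least,135,0.13,49,0.43,115,0.06,11,0.78,132,0.17,135,0.15
SWE,Sweden,least,136,0.11,37,0.47,116,0.06,3,0.85,136,0.16,136,0.13
KOR,Republic of Korea,least,137,0.11,145,0.10,108,0.09,25,0.51,138,0.14,137,0.13
BEL,Belgium,least,138,0.11,110,0.28,122,0.05,18,0.65,134,0.16,138,0.12
GBR,United Kingdom,least,139,0.11,90,0.33,119,0.05,17,0.70,135,0.16,139,0.12
CHE,Switzerland,least,140,0.10,57,0.42,107,0.09,4,0.85,142,0.12,140,0.12
FIN,Finland,least,141,0.08,48,0.43,121,0.05,2,0.86,140,0.13,142,0.09
NOR,Norway,least,142,0.07,74,0.36,109,0.08,6,0.83,143,0.10,141,0.09
DEU,Germany,least,143,0.06,84,0.34,131,0.01,13,0.77,141,0.12,144,0.06
CAN,Canada,least,144,0.06,118,0.26,104,0.12,10,0.79,146,0.06,143,0.08
DNK,Denmark,least,145,0.05,77,0.35,123,0.05,7,0.83,144,0.10,145,0.06
AUT,Austria,least,146,0.05,106,0.29,118,0.05,12,0.77,145,0.09,146,0.05
USA,United States of America,least,147,0.00,78,0.35,99,0.13,1,1.00,148,0.00,147,0.01
JPN,Japan,least,148,0.00,119,0.25,128,0.02,9,0.80,147,0.06,148,0.00
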