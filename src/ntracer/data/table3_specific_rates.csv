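lake,site,date,fraction,no3_per_d,nh4_per_d,urea_per_d,glu_per_d
LA,,2020-06-17,WW,,,,
LA,,2020-06-17,FL,,,,
LA,,2020-06-17,MC,,,,
LA,,2020-07-02,WW,0.0071,0.0091,0.0396,0.00060
LA,,2020-07-02,FL,0.0005,0.0061,0.0073,0.0006
LA,,2020-07-02,MC,0.0127,0.0407,0.160,0.0023
LA,,2020-07-15,WW,0.0196,0.0174,0.0355,0.00059
LA,,2020-07-15,FL,0.0012,0.0075,0.0060,0.0009
LA,,2020-07-15,MC,0.0249,0.0215,0.0347,0.0005
LA,,2020-07-29,WW,0.102,0.0487,0.203,0.00165
LA,,2020-07-29,FL,0.0136,0.0816,0.0639,0.0051
LA,,2020-07-29,MC,0.203,0.118,0.4341,0.0027
LA,,2020-08-13,WW,0.0145,0.0338,0.0902,0.00055
LA,,2020-08-13,FL,0.0276,0.155,0.282,0.0033
LA,,2020-08-13,MC,0.0232,0.0579,0.147,0.0011
LA,,2020-08-26,WW,0.163,0.156,0.502,0.0021
LA,,2020-08-26,FL,0.0118,0.0932,0.177,0.0032
LA,,2020-08-26,MC,0.139,0.238,0.78,0.0029
LA,,2020-09-09,WW,0.0178,0.0137,0.0481,0.00039
LA,,2020-09-09,FL,0.0021,0.0130,0.0242,0.0013
LA,,2020-09-09,MC,0.0793,0.0616,0.242,0.0017
LA,,2020-09-21,WW,0.100,0.0693,0.0799,0.0023
LA,,2020-09-21,FL,0.125,0.0392,0.0120,0.0025
LA,,2020-09-21,MC,0.0007,0.167,0.261,0.0037
LA,,2020-10-08,WW,0.080,0.0407,,0.0016
LA,,2020-10-08,FL,0.0069,0.0451,,0.0034
LA,,2020-10-08,MC,0.1208,0.0628,,0.0015
LA,,2020-10-19,WW,0.185,0.0379,0.180,0.0017
LA,,2020-10-19,FL,0.0156,0.0165,0.0279,0.0020
LA,,2020-10-19,MC,0.0892,0.0538,0.0690,0.0018
LA,,2020-10-27,WW,0.0511,0.0314,0.174,
LA,,2020-10-27,FL,0.0045,0.0153,0.0354,
LA,,2020-10-27,MC,0.0475,0.0611,0.3410,
LA,,2020-11-17,WW,0.0019,0.0401,0.0363,
LA,,2020-11-17,FL,0.0034,0.0091,0.0113,
LA,,2020-11-17,MC,0.0026,0.0531,0.0193,
LA,,2021-07-14,WW,0.0069,0.0086,0.0396,0.00083
LA,,2021-07-14,FL,0.0044,0.0174,0.0345,0.0043
LA,,2021-07-14,MC,0.0086,0.0111,0.0515,0.0010
LA,,2021-07-28,WW,0.0521,0.0505,0.223,0.0050
LA,,2021-07-28,FL,0.0040,0.0221,0.0170,0.0049
LA,,2021-07-28,MC,0.0221,0.0693,0.31,0.0046
LA,,2022-08-02,WW,0.0453,0.293,0.152,0.0021
LA,,2022-08-02,FL,0.0264,0.420,0.110,0.0068
LA,,2022-08-02,MC,0.0469,0.295,0.170,0.0025
LA,,2022-09-07,WW,0.578,0.672,0.596,0.0156
LA,,2022-09-07,FL,0.0396,0.463,0.132,0.0342
LA,,2022-09-07,MC,0.238,0.822,0.674,0.0106
LCP,,2021-07-21,WW,0.0297,0.0538,0.306,0.0049
LCP,,2021-07-21,FL,0.0037,0.0767,0.436,0.0052
LCP,,2021-07-21,MC,0.0062,0.0200,0.0994,0.0035
LCP,,2021-08-04,WW,0.0035,0.0073,0.0703,0.0009
LCP,,2021-08-04,FL,0.0001,0.00046,0.0033,0.00012
LCP,,2021-08-04,MC,0.0499,0.106,0.953,0.014
LCP,,2021-10-14,WW,0.0309,0.0135,0.0137,0.0008
LCP,,2021-10-14,FL,0.0002,0.00027,0.00028,0.00012
LCP,,2021-10-14,MC,0.451,0.336,,1.47
LCP,,2022-07-27,WW,0.113,0.122,0.0524,0.0029
LCP,,2022-07-27,FL,0.00482,0.0377,0.00626,0.0019
LCP,,2022-07-27,MC,0.802,2.78,0.337,0.0132
LCP,,2022-08-11,WW,0.0116,0.255,0.0487,0.0027
LCP,,2022-08-11,FL,0.00087,0.0251,0.0049,0.0006
LCP,,2022-08-11,MC,0.0057,2.26,,
LCP,,2022-09-02,WW,0.0491,0.282,0.0925,0.0020
LCP,,2022-09-02,FL,0.00051,0.00866,0.00206,0.00037
LCP,,2022-09-02,MC,0.625,3.44,0.977,0.028
LE,M1,2021-08-19,WW,0.0366,0.0203,0.124,0.0139
LE,M1,2021-08-19,FL,0.0492,0.103,0.303,0.0712
LE,M1,2021-08-19,MC,0.0347,0.030,0.135,0.0072
LE,M2,2022-08-18,WW,0.122,0.373,1.34,0.0402
LE,M2,2022-08-18,FL,0.0662,1.02,2.89,0.135
LE,M2,2022-08-18,MC,0.119,0.676,2.30,0.0505
LE,M2,2022-08-19,WW,0.0978,0.0521,0.321,0.0154
LE,M2,2022-08-19,FL,0.0244,0.0195,0.124,0.0390
LE,M2,2022-08-19,MC,0.0166,0.0118,0.0569,0.0014
HE,,2021-09-16,WW,0.0089,0.063,0.0852,0.0057
HE,,2021-09-16,FL,0.0053,0.0829,0.129,0.0043
HE,,2021-09-16,MC,0.0075,0.296,0.386,0.0383
NT,,2021-09-17,WW,0.106,0.0645,0.256,0.0040
NT,,2021-09-17,FL,0.0262,0.0418,0.153,0.0046
NT,,2021-09-17,MC,0.0455,0.157,0.531,0.0056
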