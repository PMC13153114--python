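lake,site,date,surface_temp_c,microcystin_ug_l,nitrate_um,ammonia_um,urea_um,glutamic_acid_um,glu_flag,orthophosphate_um,tn_um,tp_um
LA,,2020-06-17,22.1,11,17.63,9.28,1.41,0.01,1,0.67,,
LA,,2020-07-02,27.1,27,0.21,0.40,1.06,0.01,1,6.05,257.82,8.02
LA,,2020-07-15,26.0,35,0.56,0.99,0.85,0.01,1,3.33,239.83,11.44
LA,,2020-07-29,29.9,23,0.67,0.59,1.11,0.01,1,1.67,,
LA,,2020-08-13,28.9,103,0.12,1.16,1.25,0.01,1,,401.12,
LA,,2020-08-26,25.1,12,0.81,1.65,2.43,0.01,1,2.72,153.73,6.85
LA,,2020-09-09,25.7,94,0.18,0.49,1.26,0.01,1,,,
LA,,2020-09-21,16.2,21,0.55,0.63,0.64,0.01,1,,,
LA,,2020-10-08,16.5,59,0.49,1.13,,0.01,1,,,
LA,,2020-10-19,14.9,33,2.32,0.68,1.20,0.01,1,0.73,,
LA,,2020-10-27,15.0,49,0.38,0.70,1.60,0.57,0,0.81,,
LA,,2020-11-17,13.3,22,10.09,11.73,1.40,0.67,0,0.83,,
LA,,2021-06-16,23.3,36,32.03,6.42,1.17,,0,0.90,191.64,4.01
LA,,2021-06-23,22.7,60,0.99,1.01,0.65,,0,0.26,275.17,7.77
LA,,2021-06-30,26.5,30,0.30,1.15,2.04,,0,0.27,112.55,5.44
LA,,2021-07-08,26.3,274,0.00,0.71,0.96,,0,0.17,1130.10,41.05
LA,,2021-07-14,23.7,244,1.23,1.00,1.24,0.034,1,0.19,765.76,32.87
LA,,2021-07-28,27.0,25,1.30,0.89,1.07,0.034,1,0.21,173.01,6.38
LA,,2021-08-11,25.3,26,,,,,0,,,
LA,,2022-08-02,24.9,218,1.63,9.60,2.13,0.071,0,3.51,675.16,50.50
LA,,2022-08-26,26.9,28,1.56,1.96,0.75,0.072,0,2.42,186.90,8.02
LA,,2022-09-07,23.0,22,3.19,3.18,1.28,0.074,0,0.68,154.34,5.60
LA,,2022-09-23,19.8,31,3.28,1.80,0.66,0.069,0,0.79,222.02,7.46
LA,,2022-10-05,14.3,28,7.71,1.80,0.00,0.067,0,0.36,121.55,4.29
LCP,,2020-10-07,17.7,8,,,,,0,,,
LCP,,2021-07-21,27.2,8,1.02,1.01,1.46,0.034,1,0.71,146.67,10.11
LCP,,2021-08-04,27.2,150,0.86,1.53,3.31,0.078,0,0.80,1305.50,62.32
LCP,,2021-10-14,18.9,503,3.15,1.02,0.74,0.089,0,0.77,1390.31,
LCP,,2022-06-28,24.3,127,2.60,10.99,2.64,0.068,0,2.73,810.10,44.24
LCP,,2022-07-27,27.0,35,3.76,3.82,0.42,0.059,0,0.69,272.77,19.12
LCP,,2022-08-11,29.7,130,5.28,22.45,1.85,0.113,0,0.40,2051.48,
LCP,,2022-09-02,25.3,45,2.36,12.99,1.66,0.109,0,2.33,667.45,34.71
LCP,,2022-09-14,23.4,29,1.53,3.27,2.94,0.072,0,1.47,267.42,13.38
LCP,,2022-09-28,18.7,7,3.65,1.62,0.95,0.079,0,1.33,162.48,9.65
LE,M1,2021-08-19,25.9,,44.58,0.60,1.51,0.315,0,0.58,196.14,3.55
LE,M2,2022-08-18,23.0,11,19.38,1.35,2.80,0.226,0,0.28,157.34,4.37
LE,M2,2022-08-19,23.6,8,1.06,1.77,2.08,0.226,0,0.46,141.06,3.41
HE,,2021-09-16,22.0,2,0.34,1.40,0.69,0.085,0,0.27,102.55,7.45
NT,,2021-09-17,21.6,10,2.17,1.01,1.30,0.034,1,0.31,121.44,2.81
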