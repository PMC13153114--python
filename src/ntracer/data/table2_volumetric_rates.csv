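lake,site,date,fraction,no3_umol_l_h,nh4_umol_l_h,urea_umol_l_h,glu_umol_l_h
LA,,2020-06-17,WW,12.1,4.31,2.17,0.010
LA,,2020-06-17,FL,2.94,1.74,0.92,0.013
LA,,2020-06-17,MC,0.99,3.10,1.13,0.059
LA,,2020-07-02,WW,0.31,0.39,1.72,0.026
LA,,2020-07-02,FL,0.00,0.05,0.06,0.005
LA,,2020-07-02,MC,0.52,1.68,6.61,0.096
LA,,2020-07-15,WW,0.71,0.63,1.28,0.021
LA,,2020-07-15,FL,0.01,0.07,0.06,0.009
LA,,2020-07-15,MC,0.76,0.65,1.05,0.014
LA,,2020-07-29,WW,0.73,0.35,1.46,0.012
LA,,2020-07-29,FL,0.01,0.08,0.06,0.005
LA,,2020-07-29,MC,1.16,0.67,2.48,0.015
LA,,2020-08-13,WW,0.28,0.65,1.74,0.011
LA,,2020-08-13,FL,0.03,0.15,0.27,0.003
LA,,2020-08-13,MC,0.47,1.18,3.00,0.023
LA,,2020-08-26,WW,0.84,0.81,2.59,0.011
LA,,2020-08-26,FL,0.01,0.10,0.19,0.004
LA,,2020-08-26,MC,0.65,1.12,3.68,0.014
LA,,2020-09-09,WW,0.66,0.51,1.78,0.014
LA,,2020-09-09,FL,0.00,0.02,0.04,0.002
LA,,2020-09-09,MC,2.10,1.63,6.41,0.046
LA,,2020-09-21,WW,0.70,0.48,0.55,0.016
LA,,2020-09-21,FL,0.21,0.07,0.02,0.004
LA,,2020-09-21,MC,0.00,0.78,1.22,0.017
LA,,2020-10-08,WW,0.81,0.41,,0.016
LA,,2020-10-08,FL,0.01,0.06,,0.004
LA,,2020-10-08,MC,1.02,0.53,,0.013
LA,,2020-10-19,WW,1.53,0.31,1.48,0.014
LA,,2020-10-19,FL,0.02,0.02,0.04,0.003
LA,,2020-10-19,MC,0.78,0.47,0.60,0.016
LA,,2020-10-27,WW,0.53,0.33,1.82,
LA,,2020-10-27,FL,0.01,0.03,0.07,
LA,,2020-10-27,MC,0.41,0.53,2.94,
LA,,2020-11-17,WW,0.02,0.33,0.30,
LA,,2020-11-17,FL,0.01,0.02,0.02,
LA,,2020-11-17,MC,0.02,0.34,0.12,
LA,,2021-07-14,WW,0.26,0.32,1.48,0.031
LA,,2021-07-14,FL,0.01,0.02,0.04,0.005
LA,,2021-07-14,MC,0.29,0.37,1.71,0.032
LA,,2021-07-28,WW,0.29,0.28,1.25,0.028
LA,,2021-07-28,FL,0.01,0.03,0.03,0.007
LA,,2021-07-28,MC,0.10,0.31,1.39,0.021
LA,,2022-08-02,WW,1.74,11.3,5.83,0.083
LA,,2022-08-02,FL,0.03,0.54,0.14,0.009
LA,,2022-08-02,MC,1.80,11.4,6.53,0.098
LA,,2022-09-07,WW,3.58,4.16,3.69,0.097
LA,,2022-09-07,FL,0.03,0.34,0.10,0.025
LA,,2022-09-07,MC,1.22,4.21,3.45,0.054
LCP,,2021-07-21,WW,0.17,0.31,1.73,0.028
LCP,,2021-07-21,FL,0.02,0.08,0.39,0.014
LCP,,2021-07-21,MC,0.01,0.15,0.84,0.01
LCP,,2021-08-04,WW,0.21,0.44,4.18,0.055
LCP,,2021-08-04,FL,0.01,0.03,0.19,0.007
LCP,,2021-08-04,MC,0.22,0.46,4.15,0.061
LCP,,2021-10-14,WW,2.01,0.88,0.89,0.050
LCP,,2021-10-14,FL,0.01,0.02,0.02,0.007
LCP,,2021-10-14,MC,0.91,0.68,,2.96
LCP,,2022-07-27,WW,1.62,1.75,0.75,0.042
LCP,,2022-07-27,FL,0.05,0.4,0.07,0.02
LCP,,2022-07-27,MC,1.61,5.61,0.68,0.027
LCP,,2022-08-11,WW,0.35,7.60,1.45,0.081
LCP,,2022-08-11,FL,0.02,0.47,0.09,0.011
LCP,,2022-08-11,MC,0.02,6.93,,
LCP,,2022-09-02,WW,1.38,7.95,2.61,0.057
LCP,,2022-09-02,FL,0.01,0.25,0.06,0.011
LCP,,2022-09-02,MC,3.13,17.2,4.89,0.14
LE,M1,2021-08-19,WW,0.33,0.18,1.11,0.124
LE,M1,2021-08-19,FL,0.04,0.08,0.23,0.055
LE,M1,2021-08-19,MC,0.17,0.14,0.65,0.035
LE,M2,2022-08-18,WW,0.56,1.71,6.14,0.185
LE,M2,2022-08-18,FL,0.07,1.06,2.98,0.140
LE,M2,2022-08-18,MC,0.29,1.67,5.67,0.125
LE,M2,2022-08-19,WW,0.12,2.30,5.65,0.234
LE,M2,2022-08-19,FL,0.02,1.58,3.65,0.140
LE,M2,2022-08-19,MC,0.09,2.68,7.05,0.184
HE,,2021-09-16,WW,0.08,0.54,0.72,0.048
HE,,2021-09-16,FL,0.01,0.23,0.30,0.029
HE,,2021-09-16,MC,0.04,0.58,0.90,0.030
NT,,2021-09-17,WW,0.71,0.43,1.71,0.027
NT,,2021-09-17,FL,0.08,0.12,0.45,0.014
NT,,2021-09-17,MC,0.14,0.49,1.65,0.018
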