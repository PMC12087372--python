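sex,age,p5,p10,p25,p50,p75,p90,p95
female,40,0.03,0.07,0.16,0.39,0.83,1.41,2.02
female,45,0.06,0.11,0.26,0.57,1.13,1.84,2.58
female,50,0.09,0.18,0.40,0.83,1.53,2.47,3.45
female,55,0.14,0.27,0.59,1.16,2.09,3.44,4.85
female,60,0.21,0.38,0.83,1.59,2.86,5.02,7.26
female,65,0.31,0.56,1.17,2.22,4.18,7.96,11.98
female,70,0.49,0.86,1.70,3.32,6.77,13.91,21.73
female,75,0.76,1.32,2.50,5.00,10.80,23.03,36.25
female,80,1.13,1.89,3.61,7.29,15.59,32.86,49.78
female,85,1.61,2.56,5.14,10.31,20.73,41.52,58.38
male,40,0.03,0.06,0.14,0.35,0.74,1.28,1.86
male,45,0.05,0.10,0.22,0.50,0.95,1.61,2.34
male,50,0.09,0.15,0.34,0.71,1.27,2.12,3.11
male,55,0.13,0.23,0.52,1.00,1.74,2.95,4.40
male,60,0.20,0.34,0.76,1.40,2.48,4.37,6.69
male,65,0.26,0.48,1.06,1.98,3.70,6.86,10.77
male,70,0.31,0.63,1.38,2.87,5.72,11.12,17.83
male,75,0.36,0.82,1.78,4.08,8.60,17.24,27.38
male,80,0.48,1.15,2.37,5.52,12.00,24.28,36.53
male,85,0.69,1.69,3.26,7.17,15.78,31.66,43.61
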