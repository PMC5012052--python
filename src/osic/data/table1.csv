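case_id,implant_id,source,proj_a1,proj_a2,saf_a1,saf_a2,saf_a3,saf_a4
7,8,observer1_rep1,35.67,20.60,16.33,11.54,17.52,5.60
7,8,observer1_rep2,34.59,22.66,15.90,11.90,17.42,5.65
7,8,observer2_rep1,34.72,21.36,16.48,11.29,17.46,5.41
7,8,observer2_rep2,34.39,21.43,16.59,11.16,17.44,5.51
7,8,gold_standard,34.51,21.42,16.50,11.25,17.38,5.51
3,3,observer1_rep1,35.78,33.80,13.38,10.29,4.02,4.58
3,3,observer1_rep2,35.69,34.34,13.01,9.99,4.51,4.49
3,3,observer2_rep1,35.21,33.77,13.02,10.51,4.19,4.46
3,3,observer2_rep2,35.60,34.52,13.45,10.27,4.23,4.39
3,3,gold_standard,35.61,34.30,13.20,10.19,4.15,4.44
22,1,observer1_rep1,25.67,23.66,44.28,12.71,7.68,9.30
22,1,observer1_rep2,25.63,24.04,44.54,13.38,7.75,9.31
22,1,observer2_rep1,25.39,24.06,44.23,13.34,7.35,9.34
22,1,observer2_rep2,25.28,23.96,44.76,13.50,7.37,9.42
22,1,gold_standard,25.61,24.10,44.38,13.21,7.55,9.29
18,4,observer1_rep1,41.14,37.39,24.12,21.55,40.16,15.95
18,4,observer1_rep2,43.13,37.12,23.38,21.88,41.39,14.61
18,4,observer2_rep1,43.29,38.21,23.72,21.56,40.87,15.69
18,4,observer2_rep2,42.97,37.94,24.39,20.94,40.52,15.74
18,4,gold_standard,42.81,38.27,23.54,21.63,40.65,15.83
15,0,observer1_rep1,30.03,16.73,44.61,11.91,16.48,6.62
15,0,observer1_rep2,30.30,19.61,45.86,10.82,16.29,6.25
15,0,observer2_rep1,30.32,19.99,45.61,10.72,16.29,5.63
15,0,observer2_rep2,30.00,19.42,45.57,10.69,16.46,6.04
15,0,gold_standard,29.83,19.68,45.64,10.72,16.17,6.30
25,8,observer1_rep1,26.09,14.03,17.62,19.69,13.60,3.29
25,8,observer1_rep2,26.13,15.66,17.17,19.51,13.69,3.71
25,8,observer2_rep1,26.09,15.36,16.83,19.86,13.88,3.53
25,8,observer2_rep2,25.93,15.26,17.88,19.72,13.91,3.40
25,8,gold_standard,26.08,14.93,17.35,19.85,13.81,3.41
14,7,observer1_rep1,7.22,31.70,31.87,15.80,28.14,19.85
14,7,observer1_rep2,8.18,31.95,31.35,15.50,27.73,19.16
14,7,observer2_rep1,6.99,32.51,31.19,15.04,27.42,18.81
14,7,observer2_rep2,6.90,31.16,31.37,15.46,26.99,19.56
14,7,gold_standard,7.30,31.62,31.21,15.56,27.51,19.21
16,2,observer1_rep1,32.00,35.50,11.11,17.58,13.84,3.58
16,2,observer1_rep2,31.94,35.41,11.27,17.18,13.49,3.51
16,2,observer2_rep1,31.33,35.88,11.17,17.17,13.77,3.34
16,2,observer2_rep2,31.32,35.22,11.07,17.03,13.76,3.40
16,2,gold_standard,31.33,35.34,11.21,17.09,13.74,3.41
20,2,observer1_rep1,25.62,22.77,14.24,22.02,9.19,2.45
20,2,observer1_rep2,25.82,22.91,14.15,21.81,8.81,2.31
20,2,observer2_rep1,25.65,23.38,14.28,21.86,9.08,2.08
20,2,observer2_rep2,25.69,23.27,14.14,21.73,8.87,2.25
20,2,gold_standard,25.61,23.13,14.23,21.81,9.08,2.17
5,8,observer1_rep1,39.27,11.33,9.48,8.74,18.57,0.74
5,8,observer1_rep2,39.25,10.63,9.12,8.79,18.57,0.45
5,8,observer2_rep1,38.73,11.71,9.35,8.39,18.74,0.47
5,8,observer2_rep2,39.00,11.41,9.04,8.55,18.89,0.43
5,8,gold_standard,38.98,11.06,9.22,8.60,18.80,0.38
24,7,observer1_rep1,2.96,22.15,34.91,26.15,29.58,27.10
24,7,observer1_rep2,2.34,22.61,33.99,26.90,30.00,26.41
24,7,observer2_rep1,1.59,22.94,33.46,25.97,29.66,26.49
24,7,observer2_rep2,2.19,22.25,34.04,26.72,29.27,27.36
24,7,gold_standard,2.45,22.71,33.96,26.54,29.32,26.95
2,0,observer1_rep1,15.71,20.17,45.65,11.82,11.85,11.69
2,0,observer1_rep2,15.32,20.35,46.05,12.23,12.00,12.35
2,0,observer2_rep1,15.63,20.10,45.29,11.81,11.34,11.61
2,0,observer2_rep2,15.30,19.58,45.54,12.22,11.92,11.21
2,0,gold_standard,15.49,20.00,45.66,12.04,11.97,11.48
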