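subject,group,sesc_ap_mm,sesc_ml_mm,segmental_ap_mm,segmental_ml_mm
1,fit,14.08,21.78,50.62,71.24
2,fit,19.98,15.28,43.31,39.20
3,fit,26.33,19.65,118.80,17.11
4,fit,22.70,14.81,53.06,16.07
5,fit,9.42,11.34,44.91,17.49
6,fit,32.44,18.95,53.01,42.04
7,fit,21.38,15.15,23.46,33.11
8,fit,14.68,11.68,46.18,29.77
9,fit,13.17,17.86,49.86,19.82
10,fit,19.43,19.89,45.23,31.16
11,fit,14.83,21.34,37.71,31.51
12,obese,8.60,8.33,38.62,40.73
13,obese,12.28,12.52,56.45,19.93
14,obese,20.16,12.08,23.42,14.03
15,obese,14.00,24.32,26.89,31.93
16,obese,21.26,17.22,45.15,29.86
17,obese,17.47,68.12,21.79,51.05
18,obese,13.53,11.60,53.29,20.63
19,obese,36.35,34.77,61.03,52.47
20,obese,13.74,28.98,29.40,32.13
21,obese,18.39,18.78,44.16,20.50
22,obese,22.42,20.58,32.35,33.30
23,obese,13.77,21.42,43.00,23.78
24,obese,16.78,15.27,28.82,19.31
25,obese,26.05,35.75,34.88,30.23
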