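id,n_views,manual_cm,auto_cm,re_percent
1,6,22.1,21.53,2.57
2,5,9.3,9.96,7.09
3,7,7.6,7.53,0.92
4,6,9.8,9.31,5.00
5,5,11.9,11.80,0.84
6,4,12.6,13.51,7.22
7,5,22.3,21.45,3.81
8,5,38.5,38.64,0.36
9,5,2.9,3.04,4.82
10,5,10.5,10.87,3.52
11,6,14.5,14.13,2.55
12,5,18.8,19.13,1.75
13,6,24.5,25.14,2.61
14,5,3.6,3.37,6.38
15,4,3.0,2.80,6.66
16,5,8.2,7.75,5.48
17,5,11.4,11.29,0.96
18,6,12.0,12.14,1.16
19,6,13.2,14.12,6.96
20,4,15.3,15.26,0.26
21,7,6.3,6.43,2.06
22,7,7.0,6.51,7.00
23,6,8.7,9.07,4.25
24,5,8.0,8.46,5.75
25,5,12.0,12.63,5.25
26,5,17.6,17.62,0.11
27,9,19.0,19.94,4.95
28,5,6.5,6.24,4.00
29,7,7.2,7.11,1.25
30,8,8.6,9.05,5.23
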