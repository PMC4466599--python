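age_years,sex,L,M,S
5.0,male,-1.3,15.2,0.075
5.5,male,-1.31,15.3287,0.0767
6.0,male,-1.32,15.465,0.0785
6.5,male,-1.33,15.6087,0.0803
7.0,male,-1.34,15.76,0.082
7.5,male,-1.35,15.9187,0.0837
8.0,male,-1.36,16.085,0.0855
8.5,male,-1.37,16.2587,0.0872
9.0,male,-1.38,16.44,0.089
9.5,male,-1.39,16.6288,0.0907
10.0,male,-1.4,16.825,0.0925
10.5,male,-1.41,17.0287,0.0943
11.0,male,-1.42,17.24,0.096
11.5,male,-1.43,17.4587,0.0978
12.0,male,-1.44,17.685,0.0995
12.5,male,-1.45,17.9187,0.1012
13.0,male,-1.46,18.16,0.103
13.5,male,-1.47,18.4087,0.1047
14.0,male,-1.48,18.665,0.1065
14.5,male,-1.49,18.9288,0.1082
15.0,male,-1.5,19.2,0.11
15.5,male,-1.51,19.4787,0.1117
16.0,male,-1.52,19.765,0.1135
16.5,male,-1.53,20.0587,0.1152
17.0,male,-1.54,20.36,0.117
17.5,male,-1.55,20.6687,0.1187
18.0,male,-1.56,20.985,0.1205
5.0,female,-1.5,15.0,0.08
5.5,female,-1.5075,15.1395,0.0815
6.0,female,-1.515,15.288,0.083
6.5,female,-1.5225,15.4455,0.0845
7.0,female,-1.53,15.612,0.086
7.5,female,-1.5375,15.7875,0.0875
8.0,female,-1.545,15.972,0.089
8.5,female,-1.5525,16.1655,0.0905
9.0,female,-1.56,16.368,0.092
9.5,female,-1.5675,16.5795,0.0935
10.0,female,-1.575,16.8,0.095
10.5,female,-1.5825,17.0295,0.0965
11.0,female,-1.59,17.268,0.098
11.5,female,-1.5975,17.5155,0.0995
12.0,female,-1.605,17.772,0.101
12.5,female,-1.6125,18.0375,0.1025
13.0,female,-1.62,18.312,0.104
13.5,female,-1.6275,18.5955,0.1055
14.0,female,-1.635,18.888,0.107
14.5,female,-1.6425,19.1895,0.1085
15.0,female,-1.65,19.5,0.11
15.5,female,-1.6575,19.8195,0.1115
16.0,female,-1.665,20.148,0.113
16.5,female,-1.6725,20.4855,0.1145
17.0,female,-1.68,20.832,0.116
17.5,female,-1.6875,21.1875,0.1175
18.0,female,-1.695,21.552,0.119
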