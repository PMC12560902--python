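speed_m_s,fork_length_m,tag_config,cd
0.5,1.0,none,0.138
0.5,1.5,none,0.128
0.5,2.0,none,0.123
0.5,2.5,none,0.123
0.5,2.95,none,0.121
1.0,1.0,none,0.118
1.0,1.5,none,0.110
1.0,2.0,none,0.100
1.0,2.5,none,0.097
1.0,2.95,none,0.098
1.5,1.0,none,0.110
1.5,1.5,none,0.104
1.5,2.0,none,0.093
1.5,2.5,none,0.089
1.5,2.95,none,0.089
2.0,1.0,none,0.105
2.0,1.5,none,0.099
2.0,2.0,none,0.088
2.0,2.5,none,0.082
2.0,2.95,none,0.084
3.6,1.0,none,0.096
3.6,1.5,none,0.090
3.6,2.0,none,0.081
3.6,2.5,none,0.076
3.6,2.95,none,0.074
5.0,1.0,none,0.093
5.0,1.5,none,0.085
5.0,2.0,none,0.077
5.0,2.5,none,0.074
5.0,2.95,none,0.071
7.8,1.0,none,0.085
7.8,1.5,none,0.079
7.8,2.0,none,0.072
7.8,2.5,none,0.070
7.8,2.95,none,0.067
9.1,1.0,none,0.083
9.1,1.5,none,0.077
9.1,2.0,none,0.071
9.1,2.5,none,0.069
9.1,2.95,none,0.066
0.5,1.0,archival_body,0.148
0.5,1.5,archival_body,0.131
0.5,2.0,archival_body,0.126
0.5,2.5,archival_body,0.124
0.5,2.95,archival_body,0.123
1.0,1.0,archival_body,0.120
1.0,1.5,archival_body,0.107
1.0,2.0,archival_body,0.103
1.0,2.5,archival_body,0.099
1.0,2.95,archival_body,0.098
1.5,1.0,archival_body,0.117
1.5,1.5,archival_body,0.098
1.5,2.0,archival_body,0.093
1.5,2.5,archival_body,0.090
1.5,2.95,archival_body,0.090
2.0,1.0,archival_body,0.111
2.0,1.5,archival_body,0.094
2.0,2.0,archival_body,0.088
2.0,2.5,archival_body,0.086
2.0,2.95,archival_body,0.085
3.6,1.0,archival_body,0.102
3.6,1.5,archival_body,0.087
3.6,2.0,archival_body,0.081
3.6,2.5,archival_body,0.075
3.6,2.95,archival_body,0.078
5.0,1.0,archival_body,0.097
5.0,1.5,archival_body,0.084
5.0,2.0,archival_body,0.077
5.0,2.5,archival_body,0.073
5.0,2.95,archival_body,0.073
7.8,1.0,archival_body,0.091
7.8,1.5,archival_body,0.080
7.8,2.0,archival_body,0.073
7.8,2.5,archival_body,0.069
7.8,2.95,archival_body,0.066
9.1,1.0,archival_body,0.089
9.1,1.5,archival_body,0.078
9.1,2.0,archival_body,0.071
9.1,2.5,archival_body,0.067
9.1,2.95,archival_body,0.065
0.5,2.95,fin_mount,0.143
1.0,2.95,fin_mount,0.118
1.5,2.95,fin_mount,0.109
2.0,2.95,fin_mount,0.104
3.6,2.95,fin_mount,0.096
5.0,2.95,fin_mount,0.092
7.8,2.95,fin_mount,0.086
9.1,2.95,fin_mount,0.084
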