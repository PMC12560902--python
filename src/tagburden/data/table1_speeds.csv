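speed_m_s,reynolds_number
0.5,1.39e6
1.0,2.77e6
1.5,4.16e6
2.0,5.55e6
3.6,9.99e6
5.0,1.39e7
7.8,2.16e7
9.1,2.52e7
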