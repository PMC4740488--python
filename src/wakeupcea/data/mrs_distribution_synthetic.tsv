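mrs	untreated_prob	treated_prob
0	0.2255	0.2255
1	0.2255	0.2255
2	0.18299999999999997	0.18299999999999997
3	0.14639999999999997	0.14639999999999997
4	0.1098	0.1098
5	0.07319999999999999	0.07319999999999999
6	0.036599999999999994	0.036599999999999994
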