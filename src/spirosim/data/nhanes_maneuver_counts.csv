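maneuver,n_performed,excluded_printed
1,6845,
2,7169,
3,7198,5035
4,5035,3187
5,3187,2051
6,2051,1164
7,1364,970
8,970,2
9,2,
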