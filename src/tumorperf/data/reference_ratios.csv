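model,time,ratio
1,0.10,0.021
1,0.15,0.024
1,0.30,0.42
2,0.10,0.087
2,0.15,0.167
2,0.30,4.10
3,0.10,0.141
3,0.15,0.219
3,0.30,4.65
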