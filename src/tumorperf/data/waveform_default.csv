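harmonic,cos_coeff,sin_coeff
1,0.30,0.45
2,-0.10,0.18
3,-0.06,0.04
4,-0.02,0.01
5,-0.01,0.0
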