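cx_um,cy_um,r_um
3.983569,3.469702,0.564644
4.816827,5.150212,0.531276
4.940369,1.044279,0.570413
0.674152,4.612449,0.426139
3.675684,1.277740,0.435482
2.369063,2.717216,0.604546
1.697412,1.331053,0.601191
1.382863,3.731042,0.462663
5.307179,2.848198,0.428830
2.278888,4.499374,0.469788
0.728033,2.523526,0.486015
5.298133,3.972966,0.425263
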