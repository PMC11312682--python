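     8  Et
     1  C      0.75122668    0.05752071   -0.06268717  Et.C1          2     3     4     5
     2  C     -0.75122661   -0.05752097    0.06268737  Et.C1          1     6     7     8
     3  H      1.24721743   -0.70331800    0.54734375  Et.H1          1
     4  H      1.06168674   -0.07875581   -1.10290979  Et.H1          1
     5  H      1.09056596    1.04236856    0.27189204  Et.H1          1
     6  H     -1.09056587   -1.04236886   -0.27189281  Et.H1          2
     7  H     -1.06168777    0.07875569    1.10290980  Et.H1          2
     8  H     -1.24721656    0.70331868   -0.54734318  Et.H1          2
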