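     8  HAc
     1  C     -0.96242295   -0.04221353   -0.01191140  HAc.C1         2     5     6     7
     2  C      0.49593677    0.27497735   -0.04569687  HAc.C2         1     3     4
     3  O      0.99691964    1.36549007   -0.25822575  HAc.O1         2
     4  O      1.26195186   -0.80568534    0.19187223  HAc.O2         2     8
     5  H     -1.53512999    0.86811970   -0.21048672  HAc.H1         1
     6  H     -1.23690389   -0.41862286    0.97656914  HAc.H1         1
     7  H     -1.19931818   -0.77890046   -0.78346209  HAc.H1         1
     8  H      2.17896674   -0.46316493    0.14134147  HAc.H2         4
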