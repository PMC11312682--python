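     5  Me
     1  C      0.00000000    0.00000000    0.00000000  Me.C1          2     3     4     5
     2  H     -0.30831291    0.87923842   -0.56989688  Me.H1          1
     3  H      0.11981694   -0.84886943   -0.67673044  Me.H1          1
     4  H     -0.76113332   -0.23476593    0.74730216  Me.H1          1
     5  H      0.94962929    0.20439694    0.49932515  Me.H1          1
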