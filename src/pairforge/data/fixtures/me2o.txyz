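     9  Me2O
     1  C     -1.14545879    0.26310911    0.03390596  Me2O.C1        2     4     5     6
     2  O     -0.02588675   -0.08758820    0.83595004  Me2O.O1        1     3
     3  C      1.14289991   -0.27176710    0.04872658  Me2O.C1        2     7     8     9
     4  H     -1.36554033   -0.53180789   -0.68525691  Me2O.H1        1
     5  H     -0.96071376    1.20555117   -0.49068568  Me2O.H1        1
     6  H     -2.01166910    0.39164141    0.68846455  Me2O.H1        1
     7  H      1.40148171    0.65341644   -0.47538699  Me2O.H1        3
     8  H      1.96823180   -0.53861231    0.71424047  Me2O.H1        3
     9  H      0.99665531   -1.08394263   -0.66995801  Me2O.H1        3
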