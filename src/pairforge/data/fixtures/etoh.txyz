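     9  EtOH
     1  C     -0.99984721    0.12746922   -0.18558869  EtOH.C1        2     4     5     6
     2  C      0.45485768    0.17436366    0.23034907  EtOH.C2        1     3     7     8
     3  O      1.12507582   -0.95801692   -0.30273122  EtOH.O1        2     9
     4  H     -1.08915329    0.12254473   -1.27696384  EtOH.H1        1
     5  H     -1.54691109    0.98799710    0.20948737  EtOH.H1        1
     6  H     -1.47527547   -0.79016467    0.17637060  EtOH.H1        1
     7  H      0.93456913    1.08022864   -0.15220378  EtOH.H1        2
     8  H      0.54324201    0.15522678    1.32070754  EtOH.H1        2
     9  H      2.05344243   -0.89964854   -0.01942704  EtOH.H2        3
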