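     3  H2O
     1  O      0.00644875    0.39776278    0.00000000  H2O.O1         2     3
     2  H      0.76014315   -0.21125754    0.00000000  H2O.H1         1
     3  H     -0.76659191   -0.18650524    0.00000000  H2O.H1         1
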