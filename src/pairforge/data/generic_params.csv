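type,element,sigma,epsilon,charge
Et.C1,C,3.508127,0.067797,0.000000
Et.H1,H,2.645834,0.021574,0.000000
EtOH.C1,C,3.508127,0.067797,0.000000
EtOH.C2,C,3.508127,0.067797,0.280000
EtOH.H1,H,2.645834,0.021574,0.000000
EtOH.H2,H,2.328630,0.021574,0.400000
EtOH.O1,O,3.169950,0.076255,-0.680000
H2O.H1,H,2.328630,0.021574,0.430000
H2O.O1,O,3.347016,0.076255,-0.860000
HAc.C1,C,3.508127,0.067797,0.061000
HAc.C2,C,3.549164,0.067797,0.659000
HAc.H1,H,2.645834,0.021574,0.000000
HAc.H2,H,2.328630,0.021574,0.500000
HAc.O1,O,3.111761,0.076255,-0.570000
HAc.O2,O,3.169950,0.076255,-0.650000
Me.C1,C,3.508127,0.067797,0.000000
Me.H1,H,2.645834,0.021574,0.000000
Me2O.C1,C,3.508127,0.067797,0.280000
Me2O.H1,H,2.645834,0.021574,0.000000
Me2O.O1,O,3.169950,0.076255,-0.560000
MeOH.C1,C,3.508127,0.067797,0.280000
MeOH.H1,H,2.645834,0.021574,0.000000
MeOH.H2,H,2.328630,0.021574,0.400000
MeOH.O1,O,3.169950,0.076255,-0.680000
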