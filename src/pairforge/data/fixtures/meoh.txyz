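     6  MeOH
     1  C     -0.36956410   -0.03417864   -0.00764367  MeOH.C1        2     3     4     5
     2  O      0.96919406   -0.43599777   -0.23252260  MeOH.O1        1     6
     3  H     -0.56906214    0.89243112   -0.55144153  MeOH.H1        1
     4  H     -0.53072221    0.11689441    1.06255544  MeOH.H1        1
     5  H     -1.04089720   -0.81719730   -0.36794222  MeOH.H1        1
     6  H      1.54105158    0.27804818    0.09699457  MeOH.H2        2
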