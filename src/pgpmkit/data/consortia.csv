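consortium,member
MC_A,Azotobacter chroococcum LS132
MC_A,Bacillus licheniformis PS141
MC_A,Paraburkholderia tropica MDIIIAzo225
MC_A,Pseudomonas granadensis A23/T3c
MC_A,Komagataella pastoris PP59
MC_A,Trichoderma harzianum TH01
MC_B,Azotobacter vinelandii DSM 2289
MC_B,Bacillus sp. BV84
MC_B,Bacillus amyloliquefaciens LMG 9814
MC_B,Pseudomonas fluorescens DR54
MC_B,Rahnella aquatilis BB23/T4d
MC_C,Azotobacter chroococcum LS132
MC_C,Bacillus amyloliquefaciens LMG 9814
MC_C,Burkholderia ambifaria MCI 7
MC_C,Rahnella aquatilis BB23/T4d
MC_C,Pseudomonas fluorescens DR54
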