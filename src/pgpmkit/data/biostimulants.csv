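strain,BS1,BS2,BS3,BS4
Azotobacter chroococcum LS132,+,+,-,nc
Azotobacter vinelandii DSM 2289,+,+,-,nc
Bacillus sp. BV84,+,+,-,nc
Bacillus amyloliquefaciens LMG 9814,+,+,-,nc
Bacillus licheniformis PS141,-,+,-,nc
Burkholderia ambifaria MCI 7,+,+,-,nc
Paraburkholderia tropica MDIIIAzo225,-,+,-,nc
Pichia pastoris PP59,-,+,-,nc
Pseudomonas sp. A23/T3c,+,+,-,nc
Pseudomonas fluorescens DR54,+,+,-,nc
Rahnella aquatilis BB23/T4d,-,+,-,nc
Trichoderma harzianum TH01,+,+,+,nc
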