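strain,Agrobacterium radiobacter AR39,Azospirillum brasilense ATCC 29710,Azospirillum brasilense NCCB 78036,Azotobacter chroococcum DSM 2286,Azotobacter chroococcum LS132,Azotobacter chroococcum LS136,Azotobacter vinelandii DSM 2289,Bacillus sp. BV84,Bacillus amyloliquefaciens BA41,Bacillus amyloliquefaciens LMG 9814,Bacillus licheniformis PS141,Bacillus pumilus LMG 24415,Bacillus subtilis LMG 23370,Bacillus subtilis LMG 24418,Burkholderia ambifaria LMG 11351,Burkholderia ambifaria MCI 7,Komagataella pastoris PP59,Paraburkholderia tropica MDIIIAzo225,Pseudomonas sp. PN53,Pseudomonas fluorescens DR54,Pseudomonas granadensis A23/T3c,Rahnella aquatilis BB23/T4d,Raoultella terrigena FS152
Agrobacterium radiobacter AR39,,,,,,,,,,,,,,,,,,,,,,,
Azospirillum brasilense ATCC 29710,+,,,,,,,,,,,,,,,,,,,,,,
Azospirillum brasilense NCCB 78036,+,+,,,,,,,,,,,,,,,,,,,,,
Azotobacter chroococcum DSM 2286,-,-,-,,,,,,,,,,,,,,,,,,,,
Azotobacter chroococcum LS132,+,+,+,-,,,,,,,,,,,,,,,,,,,
Azotobacter chroococcum LS136,+,+,+,-,+,,,,,,,,,,,,,,,,,,
Azotobacter vinelandii DSM 2289,+,+,+,-,+,+,,,,,,,,,,,,,,,,,
Bacillus sp. BV84,+,-,+,+,+,+,+,,,,,,,,,,,,,,,,
Bacillus amyloliquefaciens BA41,+,-,+,+,+,+,+,+,,,,,,,,,,,,,,,
Bacillus amyloliquefaciens LMG 9814,+,nc,+,-,+,+,+,+,+,,,,,,,,,,,,,,
Bacillus licheniformis PS141,+,+,+,-,+,+,+,-,-,-,,,,,,,,,,,,,
Bacillus pumilus LMG 24415,+,+,+,+,+,+,+,-,-,-,-,,,,,,,,,,,,
Bacillus subtilis LMG 23370,+,+,+,+,+,+,+,-,-,-,+,-,,,,,,,,,,,
Bacillus subtilis LMG 24418,+,+,+,+,+,+,+,-,-,-,+,-,-,,,,,,,,,,
Burkholderia ambifaria LMG 11351,+,+,+,-,+,+,+,+,+,+,+,+,+,-,,,,,,,,,
Burkholderia ambifaria MCI 7,+,-,+,-,+,+,+,+,+,+,+,+,+,+,+,,,,,,,,
Komagataella pastoris PP59,+,+,+,-,+,+,+,+,+,+,+,+,+,+,+,nc,,,,,,,
Paraburkholderia tropica MDIIIAzo225,+,+,+,-,+,+,+,+,+,nc,+,+,nc,+,+,+,+,,,,,,
Pseudomonas sp. PN53,+,+,+,+,+,+,-,-,+,+,+,+,+,+,+,+,+,+,,,,,
Pseudomonas fluorescens DR54,+,+,+,-,+,+,+,+,+,+,+,+,+,+,+,+,+,+,nc,,,,
Pseudomonas granadensis A23/T3c,+,+,+,-,+,+,+,+,+,+,+,+,+,-,+,+,+,+,+,+,,,
Rahnella aquatilis BB23/T4d,+,+,+,-,+,+,+,+,+,+,+,+,+,+,+,+,+,+,+,+,+,,
Raoultella terrigena FS152,+,+,+,-,+,+,+,+,+,+,+,+,+,+,+,+,+,+,+,+,+,+,
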