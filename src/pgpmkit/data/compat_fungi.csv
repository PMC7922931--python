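strain,Trichoderma harzianum ATCC 48131,Trichoderma harzianum TH01
Azotobacter brasilense ATCC 29710,nc,+
Azospirillum brasilense NCCB 78036,-,+
Azotobacter chroococcum DSM 2286,-,nc
Azotobacter chroococcum LS132,+,+
Agrobacterium radiobacter AR39,-,-
Azotobacter chroococcum LS163,-,+
Azotobacter vinelandii DSM 2289,+,+
Bacillus sp. BV84,-,+
Bacillus amyloliquefaciens BA41,-,-
Bacillus amyloliquefaciens LMG 9814,-,-
Bacillus licheniformis PS141,+,+
Bacillus pumilus LMG 24415,-,-
Bacillus subtilis LMG 23370,-,-
Bacillus subtilis LMG 24418,-,-
Burkholderia ambifaria LMG 11351,-,-
Burkholderia ambifaria MCI 7,-,-
Komagataella pastoris PP59,+,+
Paraburkholderia tropica MDIIIAzo225,+,nc
Pseudomonas sp. PN53,-,+
Pseudomonas granadensis A23/T3c,+,+
Pseudomonas fluorescens DR54,+,nc
Ranhella aquatilis BB23/T4d,-,+
Raoultella terrigena FS152,-,+
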