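canonical_name,aliases,kingdom,functions,selected,notes
Acaulospora morrowiae CL290,,fungus,PGP_generic,0,
Agrobacterium radiobacter AR39,Agrobacterium radiobacter AR 39,bacterium,biocontrol;PGP_generic,1,
Azospirillum brasilense ATCC 29710,Azospirillum brasilense ATTC 29710;Azotobacter brasilense ATCC 29710,bacterium,nitrogen_fixation,1,
Azospirillum brasilense NCCB 78036,,bacterium,nitrogen_fixation,1,
Azospirillum lipoferum CRT1,,bacterium,nitrogen_fixation,0,
Azotobacter chroococcum 76A,,bacterium,nitrogen_fixation,0,
Azotobacter chroococcum DSM 2286,,bacterium,nitrogen_fixation,1,
Azotobacter chroococcum LS132,,bacterium,nitrogen_fixation,1,
Azotobacter chroococcum LS163,Azotobacter chroococcum LS136,bacterium,nitrogen_fixation,1,printed as LS136 in the bacterial compatibility table; one strain with two printed codes
Azotobacter chroococcum S-5,,bacterium,nitrogen_fixation,0,
Azotobacter vinelandii DSM 2289,,bacterium,siderophore;nitrogen_fixation,1,
Bacillus sp. BV84,,bacterium,biocontrol;PGP_generic,1,
Bacillus amyloliquefaciens BA41,,bacterium,biocontrol;PGP_generic,1,
Bacillus amyloliquefaciens FZB42,,bacterium,biocontrol;PGP_generic,0,
Bacillus amyloliquefaciens LMG 9814,,bacterium,amylolytic,1,
Bacillus atrophaeus ABI02A,,bacterium,PGP_generic,0,
Bacillus licheniformis PS141,Bacillus licheniformis PS 141,bacterium,IAA_production,1,
Bacillus megaterium M3,,bacterium,P_solubilization,0,
Bacillus megaterium PMC 1855,,bacterium,P_solubilization,0,
Bacillus pumilus LMG 24415,,bacterium,PGP_generic,1,
Bacillus simplex R49538,Bacillus simple R49538,bacterium,PGP_generic;IAA_production,0,
Bacillus subtilis FZB24 WG,,bacterium,biocontrol;PGP_generic,0,
Bacillus subtilis LMG 23370,,bacterium,biocontrol;PGP_generic,1,
Bacillus subtilis LMG 24418,,bacterium,PGP_generic,1,
Bacillus subtilis OSU-142,,bacterium,nitrogen_fixation;biocontrol,0,
Burkholderia ambifaria MCI 7,,bacterium,PGP_generic,1,
Burkholderia ambifaria LMG 11351,Burkholderia ambifaria PHP7/LMG 11351;Burkholderia ambifaria PHP7,bacterium,PGP_generic,1,
Gigaspora gigantea PA125,,fungus,PGP_generic,0,
Gigaspora rosea NY328A,,fungus,PGP_generic,0,
Komagataella pastoris PP59,Pichia pastoris PP59,yeast,PGP_generic,1,
Paenibacillus sp. R47065,Paenibacillus sp R47065,bacterium,PGP_generic;IAA_production,0,
Paraburkholderia tropica MDIIIAzo225,Paraburkholderia tropica MDIIAzo225,bacterium,nitrogen_fixation,1,
Pseudomonas granadensis A23/T3c,Pseudomonas sp. A23/T3c;Pseudomonas fluorescens A23/T3c,bacterium,PGP_generic,1,
Pseudomonas fluorescens DR54,,bacterium,biocontrol;P_solubilization,1,P_solubilization supported by narrative (soluble-P increase in maize field trials) rather than the strain table
Pseudomonas putida P1-20/08,Pseudomonas putid P1-20/08,bacterium,PGP_generic,0,
Pseudomonas sp. PN53,,bacterium,PGP_generic,1,
Rahnella aquatilis BB23/T4d,Enterobacter sp. BB23/T4d;Ranhella aquatilis BB23/T4d,bacterium,PGP_generic,1,
Raoultella terrigena FS152,,bacterium,phytase;siderophore,1,
Rhizophagus intraradices FR121,,fungus,PGP_generic,0,
Septoglomus constrictum FL328,,fungus,PGP_generic,0,
Streptomyces sp. SA 51,,bacterium,biocontrol,0,
Trichoderma gamsii 6085,,fungus,biocontrol,0,
Trichoderma harzianum OmG-08,,fungus,P_solubilization,0,
Trichoderma harzianum OmG-16,,fungus,P_solubilization,0,
Trichoderma harzianum T6776,,fungus,biocontrol;PGP_generic,0,
Trichoderma harzianum TH01,,fungus,PGP_generic,1,
Trichoderma harzianum ATCC 48131,Trichoderma harzianum CBS 354.33;Trichoderma harzianum CBS 354.33/ATCC 48131,fungus,biocontrol,1,chitinase production tagged as biocontrol
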