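code,name,H,Arable land,Urban land,Rural settlements,Industrial and mining land,Saline-alkali land,Bare ground
1,paddy fields,0.60,0.30,0.50,0.35,0.40,0.50,0.10
2,dry farmland,0.40,0.60,0.50,0.35,0.40,0.20,0.20
3,woodland,0.99,0.50,0.85,0.65,0.60,0.60,0.20
4,shrubland,0.99,0.30,0.70,0.60,0.50,0.60,0.10
5,sparse woodland,0.99,0.60,0.85,0.65,0.60,0.50,0.30
6,other woodlands,0.99,0.60,0.85,0.65,0.60,0.20,0.30
7,high coverage grassland,0.75,0.40,0.60,0.40,0.50,0.25,0.20
8,medium coverage grass,0.70,0.50,0.70,0.50,0.55,0.30,0.30
9,low coverage grassland,0.60,0.50,0.80,0.60,0.55,0.30,0.30
10,river,0.99,0.50,0.90,0.70,0.80,0.25,0.15
11,lake,0.90,0.50,0.90,0.75,0.80,0.20,0.15
12,reservoirs,0.90,0.60,0.90,0.75,0.80,0.20,0.15
13,mudflat,0.70,0.70,0.60,0.60,0.30,0.20,0.30
14,urban area,0.00,0.00,0.00,0.00,0.00,0.00,0.00
15,rural settlements,0.00,0.00,0.00,0.00,0.00,0.00,0.00
16,other construction land,0.10,0.00,0.00,0.00,0.00,0.00,0.00
17,sandy land,0.00,0.00,0.00,0.00,0.00,0.00,0.00
18,saline-alkali land,0.50,0.20,0.20,0.15,0.15,0.15,0.10
19,wetlands,0.65,0.70,0.50,0.20,0.20,0.30,0.30
20,bare land,0.05,0.00,0.00,0.00,0.00,0.00,0.00
21,bare rock texture,0.05,0.00,0.00,0.00,0.00,0.00,0.00
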