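# Sub-threshold compounds retained on pharmacological grounds
# (reported oxytocin / uterine-contraction / vascular relevance),
# one compound name per line.
()-alpha-Terpineol
()-Terpinen-4-ol
(L)-alpha-Terpineol
(R)-Linalool
(Z)-Ligustilide
1-Terpineol
ADO
Adenine
BdPh
Caffeic acid
Coniferyl ferulate
FA
Ferulic acid (CIS)
Nicotinic acid
PLO
Senkyunolide A
Sphingomyelin
Succinic acid
Sucrose
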