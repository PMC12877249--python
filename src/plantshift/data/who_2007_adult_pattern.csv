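# WHO/FAO/UNU 2007 amino acid scoring pattern for adults (mg per g protein).
# Sulfur amino acids (saa) pool Met+Cys; aromatic amino acids (aaa) pool Phe+Tyr.
# Swap in another pattern via load_reference_pattern(path).
iaa,mg_per_g_protein
his,15
ile,30
leu,59
lys,45
saa,22
aaa,38
thr,23
trp,6
val,39
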