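# Name suffix -> molecule_type for biotherapeutic classification.
# suffix<TAB>molecule_type
mab	antibody
ase	enzyme
gene	gene
cel	cell-based
cept	protein
kin	protein
mer	oligonucleotide
rsen	oligonucleotide
siran	oligonucleotide
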