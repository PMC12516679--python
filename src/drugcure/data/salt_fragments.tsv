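# Common counterions and solvents stripped when deriving a parent compound.
# SMILES<TAB>name  (connectivity-level match, charge-normalized)
Cl	hydrochloric acid
Br	hydrobromic acid
I	hydriodic acid
F	hydrofluoric acid
O	water
[Na+]	sodium
[K+]	potassium
[Li+]	lithium
[Ca+2]	calcium
[Mg+2]	magnesium
[Zn+2]	zinc
[NH4+]	ammonium
OS(=O)(=O)O	sulfuric acid
OP(=O)(O)O	phosphoric acid
O=C(O)C(=O)O	oxalic acid
CC(=O)O	acetic acid
OC(=O)C(O)C(O)C(=O)O	tartaric acid
OC(=O)CC(O)(CC(=O)O)C(=O)O	citric acid
OC(=O)/C=C/C(=O)O	fumaric acid
OC(=O)/C=C\C(=O)O	maleic acid
CC(O)C(=O)O	lactic acid
OC(=O)CCC(=O)O	succinic acid
CS(=O)(=O)O	methanesulfonic acid
Cc1ccc(cc1)S(=O)(=O)O	p-toluenesulfonic acid
OS(=O)(=O)c1ccccc1	benzenesulfonic acid
OC(=O)c1ccccc1	benzoic acid
OC(=O)C(O)CC(=O)O	malic acid
OCC(O)CO	glycerol
CCO	ethanol
CO	methanol
CC(C)O	isopropanol
O=C(O)CCCCC(=O)O	adipic acid
OC(=O)c1cc(O)ccc1	salicylic acid variant
[O-][N+](=O)O	nitric acid
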