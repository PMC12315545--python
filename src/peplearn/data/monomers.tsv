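code	smiles	is_canonical	side_chain_atoms
A	[*:1]N[C@@H](C)C(=O)[*:2]	true
R	[*:1]N[C@@H](CCCNC(=N)N)C(=O)[*:2]	true
N	[*:1]N[C@@H](CC(N)=O)C(=O)[*:2]	true
D	[*:1]N[C@@H](CC(O)=O)C(=O)[*:2]	true
C	[*:1]N[C@@H](CS)C(=O)[*:2]	true
E	[*:1]N[C@@H](CCC(O)=O)C(=O)[*:2]	true
Q	[*:1]N[C@@H](CCC(N)=O)C(=O)[*:2]	true
G	[*:1]NCC(=O)[*:2]	true
H	[*:1]N[C@@H](Cc1c[nH]cn1)C(=O)[*:2]	true
I	[*:1]N[C@@H]([C@@H](C)CC)C(=O)[*:2]	true
L	[*:1]N[C@@H](CC(C)C)C(=O)[*:2]	true
K	[*:1]N[C@@H](CCCCN)C(=O)[*:2]	true
M	[*:1]N[C@@H](CCSC)C(=O)[*:2]	true
F	[*:1]N[C@@H](Cc1ccccc1)C(=O)[*:2]	true
P	[*:1]N1CCC[C@H]1C(=O)[*:2]	true
S	[*:1]N[C@@H](CO)C(=O)[*:2]	true
T	[*:1]N[C@@H]([C@@H](O)C)C(=O)[*:2]	true
W	[*:1]N[C@@H](Cc1c[nH]c2ccccc12)C(=O)[*:2]	true
Y	[*:1]N[C@@H](Cc1ccc(O)cc1)C(=O)[*:2]	true
V	[*:1]N[C@@H](C(C)C)C(=O)[*:2]	true
dA	[*:1]N[C@H](C)C(=O)[*:2]	false
dF	[*:1]N[C@H](Cc1ccccc1)C(=O)[*:2]	false
meG	[*:1]N(C)CC(=O)[*:2]	false
meF	[*:1]N(C)[C@@H](Cc1ccccc1)C(=O)[*:2]	false
Aib	[*:1]NC(C)(C)C(=O)[*:2]	false
Hse	[*:1]N[C@@H](CCO)C(=O)[*:2]	false
Nle	[*:1]N[C@@H](CCCC)C(=O)[*:2]	false
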