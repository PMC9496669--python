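# Docked metabolite panel: name, PubChem CID, SMILES (structures keyed by CID)
name	cid	smiles
Equol	91469	C1[C@@H](COC2=CC(=CC=C21)O)C3=CC=C(C=C3)O
3-Indolepropionic acid	3744	C1=CC=C2C(=C1)C(=CN2)CCC(=O)O
Trimethylamine oxide	1145	C[N+](C)(C)[O-]
Butyrate	104775	CCCC(=O)[O-]
Acetate	175	CC(=O)[O-]
Indole	798	C1=CC=C2C(=C1)C=CN2
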