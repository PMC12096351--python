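compound_id,smiles,is_type1a,tbdms_count
alanine,CC(N)C(=O)O,true,0
valine,CC(C)C(N)C(=O)O,true,0
leucine,CC(C)CC(N)C(=O)O,true,0
isoleucine,CCC(C)C(N)C(=O)O,true,0
serine,OCC(N)C(=O)O,true,0
threonine,CC(O)C(N)C(=O)O,true,0
cysteine,SCC(N)C(=O)O,true,0
methionine,CSCCC(N)C(=O)O,true,0
aspartic_acid,OC(=O)CC(N)C(=O)O,true,0
glutamic_acid,OC(=O)CCC(N)C(=O)O,true,0
asparagine,NC(=O)CC(N)C(=O)O,true,0
glutamine,NC(=O)CCC(N)C(=O)O,true,0
lysine,NCCCCC(N)C(=O)O,true,0
phenylalanine,NC(Cc1ccccc1)C(=O)O,true,0
tyrosine,NC(Cc1ccc(O)cc1)C(=O)O,true,0
tryptophan,NC(Cc1c[nH]c2ccccc12)C(=O)O,true,0
histidine,NC(Cc1c[nH]cn1)C(=O)O,true,0
norvaline,CCCC(N)C(=O)O,true,0
norleucine,CCCCC(N)C(=O)O,true,0
homoserine,OCCC(N)C(=O)O,true,0
proline,OC(=O)C1CCCN1,false,0
beta_alanine,NCCC(=O)O,false,0
sarcosine,CNCC(=O)O,false,0
glycine_betaine,C[N+](C)(C)CC(=O)[O-],false,0
n_methylalanine,CC(NC)C(=O)O,false,0
glycylglycine,NCC(=O)NCC(=O)O,false,0
glycine_tbdms_ester,NCC(=O)O[Si](C)(C)C(C)(C)C,true,1
alanine_bis_tbdms,CC(N[Si](C)(C)C(C)(C)C)C(=O)O[Si](C)(C)C(C)(C)C,true,2
valine_bis_tbdms,CC(C)C(N[Si](C)(C)C(C)(C)C)C(=O)O[Si](C)(C)C(C)(C)C,true,2
leucine_n_tbdms,CC(C)CC(N[Si](C)(C)C(C)(C)C)C(=O)O,true,1
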