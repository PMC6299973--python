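substrate	rank	synonym_group_id
fe	1	iron
iron	1	iron
lysine	1	lysine
glucose	1	glucose
lactose	1	lactose
leucine	1	bcaa
leucine/valine	2	bcaa
branched-chain amino acid	2	bcaa
mg/co/ni	2	divalent-cation
aromatic amino acid	2	aromatic-aa
phosphate	1	phosphate
dipeptide	3
sugar	3
amino acid	3
peptide	3
multidrug efflux	4
protein	4
cation	4
drug	4
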