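compound_key	gene_symbol	target_name
VFLDPWHFBUODDF-FCXRPNKRSA-N	CFTR	Cystic fibrosis transmembrane conductance regulator
16220172	CFTR	Cystic fibrosis transmembrane conductance regulator
QTQAWLPCGQOSGP-GBTDJJJQSA-N	HSP90AA1	Heat shock protein HSP 90-alpha
VFLDPWHFBUODDF-FCXRPNKRSA-N	KEAP1	Kelch-like ECH-associated protein 1
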