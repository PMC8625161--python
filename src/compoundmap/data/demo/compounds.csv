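compound_id,inchikey,smiles,cas_number,pubchem_cid,names
CAND0001,VFLDPWHFBUODDF-FCXRPNKRSA-N,COC1=CC(=CC(=C1)O)C=CC(=O)CC(=O)C=CC2=CC(OC)=C(O)C=C2,458-37-7,969516,Curcumin|Diferuloylmethane|Turmeric yellow
CAND0002,PURKAOJPTOLRMP-UHFFFAOYSA-N,CC(C)(C)C1=CC(=C(C=C1NC(=O)C2=CNC3=CC=CC=C3C2=O)O)C(C)(C)C,873054-44-5,16220172,Ivacaftor|VX-770|Kalydeco
CAND0003,QTQAWLPCGQOSGP-GBTDJJJQSA-N,CC1=CC(=O)C=C(C)C1=O,30562-34-6,5288382,Geldanamycin|NSC 122750
CAND0004,ZZVUWRFHKOJYTH-UHFFFAOYSA-N,CN(C)CCOC(C1=CC=CC=C1)C1=CC=CC=C1,58-73-1,3100,Diphenhydramine|Benadryl
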