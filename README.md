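# compoundmap

Link an application-specific collection of candidate therapeutic compounds to
a disease map.

Drug-discovery groups often maintain their own compound databases — screening
hits, literature candidates, newly synthesized molecules — that generic
resources do not cover. A disease map, in turn, is a curated systems-biology
network of the molecular interactions relevant to one disease, encoded in
SBML (frequently with CellDesigner annotations) and explored on platforms
such as MINERVA. `compoundmap` connects the two: it harmonizes compound
identifiers (InChIKey, CAS registry number, PubChem CID, synonyms),
aggregates chemical–gene interaction assertions from CTD-style and
ChEMBL-style export tables, keeps only the interactions whose gene symbol
occurs among the map's gene-like entities, and materializes the result as a
pair of mutually transposed JSON files:

- `compound2genes.json` — compound_id → sorted target gene symbols
  (map-covered only; compounds with no map target are omitted),
- `gene2compounds.json` — map gene symbol → sorted compound_ids
  (one key per gene-like map symbol, empty list when untargeted).

With `F` the forward mapping and `R` the reverse mapping, the invariant
`g ∈ F(c) ⇔ c ∈ R(g)` is enforced at build time and re-verified on every
load. On top of the index, three query families mirror how such a linkage is
used interactively: the target overlay of one compound (or the intersection
of two, `F(a) ∩ F(b)`), the reverse search `R(g)` for a selected map entity,
and database–map coverage `|{g : R(g) ≠ ∅}| / |{g}|`.

## Worked example

A small demo dataset ships with the package: four well-known compounds
(curcumin, ivacaftor, geldanamycin, diphenhydramine), two interaction
tables, and a six-species SBML excerpt in which CFTR appears in two
compartments.

```bash
DEMO=$(python -c "import compoundmap; print(compoundmap.demo_fixture_dir())")
compoundmap build --compounds $DEMO/compounds.csv --ctd $DEMO/ctd.tsv \
    --chembl $DEMO/chembl.tsv --map $DEMO/map.xml --out demo_index
```

prints

```json
{
  "coverage_fraction": 0.75,
  "n_compounds": 4,
  "n_dropped_offmap": 1,
  "n_interactions_merged": 6,
  "n_map_entities": 6,
  "n_rows_input": 9,
  "n_rows_resolved": 9,
  "n_rows_skipped": 0,
  "n_rows_unresolved": 0,
  "n_unresolved_keys": 0
}
```

Nine interaction rows resolve against the four compounds; after cross-source
deduplication six distinct compound–gene assertions remain, one of which
(curcumin → NFKB1) points at a gene absent from the map and is dropped.
Three of the map's four gene-like symbols are targeted, hence coverage 0.75.

```bash
compoundmap search curcumin --compounds $DEMO/compounds.csv
```

returns the single matching record with its ID (`CAND0001`), InChIKey,
SMILES and synonym list. Its overlay

```bash
compoundmap targets-of CAND0001 --index demo_index --map $DEMO/map.xml
```

reports symbols `["CFTR", "HSP90AA1", "KEAP1"]` and `"n_targets": 4` — four
map entities, because the CFTR symbol fans out to both of its compartments.
`compare CAND0001 CAND0002` intersects the two target sets (here: `CFTR`),
and `compounds-for CFTR` (or the entity id `s1`) lists
`["CAND0001", "CAND0002"]`.

Synthetic datasets of any size, with a recorded planted interaction truth,
come from `compoundmap make-fixture` or `compoundmap.generate_fixture`.

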