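# Methods

## The linkage model

`compoundmap` treats compound–target linkage as a three-way join:

1. **Compound collection.** Each record carries an opaque `compound_id`
   (unique within the collection), an ordered synonym list (first element is
   the display name), and optional standard identifiers: InChIKey
   (`[A-Z]{14}-[A-Z]{10}-[A-Z]`), CAS registry number (`\d{2,7}-\d{2}-\d`),
   PubChem CID (positive integer), SMILES. Identifiers that fail their
   pattern are dropped to absent with a warning rather than rejecting the
   row: collections of study-specific compounds are routinely incomplete,
   and a partial record is still searchable by name and still resolvable
   through its remaining identifiers.

2. **Interaction assertions.** Two offline TSV dialects are consumed. The
   CTD-style dialect keys compounds by CAS number (`CasRN`, `GeneSymbol`,
   optional `ChemicalName`, `InteractionActions`; `#` comments ignored); the
   ChEMBL-style dialect keys by InChIKey or PubChem CID (`compound_key`,
   `gene_symbol`, optional `target_name`), the compound key being classified
   structurally (all digits → CID, InChIKey-shaped → InChIKey, anything else
   skipped). Resolution against the collection's qualified identifier index
   produces normalized records `(compound_id, GENE_SYMBOL, source)` with
   gene symbols uppercased and trimmed — gene symbols are the target-side
   join key, InChIKey/CAS/CID the compound-side keys. Unresolvable rows go
   into an explicit report; parsing and resolution conserve counts
   (`input = skipped + unresolved + resolved`), so nothing disappears
   silently. No interaction-type or organism filter is applied; the
   interaction-type annotation is carried verbatim as evidence.

3. **Disease map.** One entity per SBML species (levels 2–3). The entity
   class comes from a CellDesigner `class` annotation when present
   (PROTEIN/GENE/RNA, with antisense RNA folded into RNA); species without
   one — metabolites, complexes, plain SBML — are OTHER. XML handling is
   namespace-tolerant (elements matched by local name) because maps in the
   wild mix CellDesigner namespace versions. Matching between interaction
   gene symbols and map entities is uppercase exact name equality; the
   indexable symbol universe defaults to gene-like entities only
   (`gene_like_only=True`), with the flag exposed because reverse-searching
   metabolites is a legitimate, if unusual, variant.

The build intersects the deduplicated assertion set with the map's symbol
universe. Off-map assertions are excluded from both directions but counted
(`n_dropped_offmap`), compounds left with no map-covered target are omitted
from the forward file (absence encodes "0 targets" and keeps the file
small), and the reverse file keeps a key for every gene-like map symbol so
coverage is computable from it alone. Reverse keys are symbols rather than
entity ids because one symbol may be realized by several species (the same
protein in two compartments); the symbol → entity fan-out is resolved at
query time, and highlight counts are therefore per-entity. The two-compound
comparison intersects at symbol level.

## Index files

`compound2genes.json` and `gene2compounds.json` are UTF-8, sorted-key,
2-space-indented JSON, so identical content yields identical bytes; a header
block records the map file's SHA-256, the source table names, the build
timestamp (pinnable for reproducible output) and the tool version, making a
stale index detectable. JSON Schema documents for both files ship under
`src/compoundmap/schemas/`; `read_index` performs the equivalent structural
validation in code, normalizes unsorted lists with a warning, and
re-verifies transpose consistency on every load, failing with a witness pair
on contradiction.

## Synthetic data generator

`generate_fixture` emulates the full input triple with planted ground truth:
`n_compounds` compounds with format-valid random InChIKeys, unique CAS
numbers and CIDs; an SBML map with `n_genes` PROTEIN species plus two
non-gene species; and interaction tables populated by independent Bernoulli
draws — each (compound, gene) slot carries an interaction with probability
`interaction_density` (default 0.3, a moderately dense screen), is
redirected to a gene absent from the map with probability
`offmap_gene_fraction` (default 0.1), and is written to both source dialects
with probability `duplicate_source_fraction` (default 0.1, otherwise to one
chosen at random). A fifth of planted rows spell the gene symbol in lower
case to exercise normalization, and optional malformed/orphan rows exercise
the skip and unresolved paths. Everything is a pure function of the spec and
its seed, so runs are byte-reproducible.

What the generator does *not* emulate: chemically meaningful structures
(identifiers are random strings — no pipeline operation interprets their
chemistry), realistic target-degree distributions (real interaction data are
heavy-tailed; planted slots are i.i.d.), synonym ambiguity across compounds,
and gene-symbol aliasing (the generator's symbols match the map exactly or
are off-map by construction). Passing the recovery properties therefore
demonstrates the correctness of the plumbing — identifier resolution,
deduplication, overlap filtering, transposition — not robustness to noisy
real-world naming, which exact-match symbol joining inherently limits.

## Design choices on genuinely open points

- **Offline tables instead of live APIs.** All tested paths consume local
  files; this keeps the artifact hermetic and lets users substitute their
  own interaction data. No live client is included.
- **Synonym search is exact case-insensitive token match**, with substring
  matching behind an explicit `--contains` flag; fuzzy/edit-distance search
  is not implemented, keeping results deterministic.
- **SMILES matching is verbatim string equality.** Canonicalization would
  require a cheminformatics toolkit and changes search semantics; it is a
  natural extension, not a default.
- **Build-time overlap filtering.** The map intersection happens when the
  index is built, not at query time, so query cost is a dictionary lookup
  and the files stay small.
- **Identifier collisions** (two compounds sharing a CAS number) keep the
  first record and warn; duplicate `compound_id`s are a hard validation
  error.
- **Complexes** are single OTHER entities; member expansion is not
  attempted.
- **HGNC-identifier matching** via SBML CV-term annotations is a documented
  extension point; the default remains name equality, which requires nothing
  of the map beyond display names.

## Problem sizes

The test suite and acceptance script run fixtures up to 200 compounds ×
100 genes (100 random configurations for the end-to-end recovery property),
exhaustive pairwise query checks on a 50×50 fixture (1 326 comparisons), and
transpose enumeration over ~10⁴ pairs — sizes chosen to exhaust the
combinatorics of the method, which is set algebra whose cost grows linearly
in the pair count, within seconds.

## Known limitations

- Exact uppercase symbol matching misses aliased or outdated gene names; a
  curation pass or HGNC mapping layer is advisable for production maps.
- The reverse index answers by symbol, so two distinct map entities sharing
  a name are indistinguishable at the index level (they are distinguished in
  query fan-out).
- Interaction evidence is carried as free text, not modeled.
- Indices go stale as source databases evolve; the header provenance makes
  this detectable but not self-healing.
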