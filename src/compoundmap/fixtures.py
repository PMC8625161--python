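"""Synthetic fixture generation with planted ground truth.

Generates the three inputs the pipeline consumes — a compound collection CSV,
a CTD-style TSV, a ChEMBL-style TSV — plus an SBML map, together with the
exact set of planted (compound, gene) interaction pairs and which of them
point at genes absent from the map.  Because the planted truth is recorded,
an end-to-end run of parse -> resolve -> merge -> build can be checked for
exact recovery without any external data.

Everything is a pure function of the spec (including its seed): two runs with
the same spec produce byte-identical files.

Synthetic InChIKeys and CAS numbers are format-valid strings, not chemically
derived — no operation in the pipeline interprets their chemistry.  SMILES
strings are simple carbon chains for the same reason.
"""

from __future__ import annotations

import json
import random
import string
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import ValidationError

_SBML_HEADER = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2/version4" xmlns:celldesigner="http://www.sbml.org/2001/ns/celldesigner" level="2" version="4">
  <model id="{model_id}">
    <listOfCompartments>
      <compartment id="cytosol"/>
    </listOfCompartments>
    <listOfSpecies>
"""

_SBML_SPECIES_CLASSED = """      <species id="{sid}" name="{name}" compartment="cytosol">
        <annotation>
          <celldesigner:extension>
            <celldesigner:speciesIdentity>
              <celldesigner:class>{cls}</celldesigner:class>
            </celldesigner:speciesIdentity>
          </celldesigner:extension>
        </annotation>
      </species>
"""

_SBML_SPECIES_PLAIN = """      <species id="{sid}" name="{name}" compartment="cytosol"/>
"""

_SBML_FOOTER = """    </listOfSpecies>
  </model>
</sbml>
"""


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset.

    ``interaction_density`` is the probability that a given (compound, gene)
    slot carries an interaction; ``offmap_gene_fraction`` the probability that
    a planted interaction points at a gene absent from the map;
    ``duplicate_source_fraction`` the probability that an interaction appears
    in both source dialects.  ``n_malformed_rows`` / ``n_unresolved_rows``
    plant rows that the parser must skip, respectively that resolution must
    report, for count-conservation checks.
    """

    n_compounds: int
    n_genes: int
    interaction_density: float = 0.3
    offmap_gene_fraction: float = 0.1
    duplicate_source_fraction: float = 0.1
    seed: int = 0
    n_malformed_rows: int = 0
    n_unresolved_rows: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 1 or self.n_genes < 1:
            raise ValidationError("n_compounds and n_genes must be >= 1")
        for name in ("interaction_density", "offmap_gene_fraction",
                     "duplicate_source_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.n_malformed_rows < 0 or self.n_unresolved_rows < 0:
            raise ValidationError("planted bad-row counts must be >= 0")


@dataclass
class FixtureManifest:
    """Paths of the written files plus the planted interaction truth."""

    out_dir: Path
    compounds_csv: Path
    ctd_tsv: Path
    chembl_tsv: Path
    map_sbml: Path
    planted_onmap: set[tuple[str, str]] = field(default_factory=set)
    planted_offmap: set[tuple[str, str]] = field(default_factory=set)
    n_malformed_rows: int = 0
    n_unresolved_rows: int = 0

    @property
    def planted_pairs(self) -> set[tuple[str, str]]:
        return self.planted_onmap | self.planted_offmap


def _synthetic_inchikey(rng: random.Random) -> str:
    letters = string.ascii_uppercase
    return (
        "".join(rng.choice(letters) for _ in range(14))
        + "-"
        + "".join(rng.choice(letters) for _ in range(10))
        + "-N"
    )


def generate_fixture(spec: FixtureSpec, out_dir: str | Path) -> FixtureManifest:
    """Write compounds.csv, ctd.tsv, chembl.tsv and map.xml under ``out_dir``.

    Interactions are distributed across the two source dialects: each planted
    pair is emitted in one dialect chosen at random, and additionally in the
    other with probability ``duplicate_source_fraction``.  The map holds
    ``n_genes`` PROTEIN species plus two non-gene (small molecule) species.
    """
    rng = random.Random(spec.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    width = max(3, len(str(spec.n_compounds - 1)))
    gwidth = max(3, len(str(spec.n_genes - 1)))
    compound_ids = [f"C{i:0{width}d}" for i in range(spec.n_compounds)]
    genes = [f"G{j:0{gwidth}d}" for j in range(spec.n_genes)]

    # compound identity table
    inchikeys = {c: _synthetic_inchikey(rng) for c in compound_ids}
    cas = {c: f"{5000 + i}-{10 + i % 90:02d}-{i % 10}" for i, c in enumerate(compound_ids)}
    cids = {c: 100000 + i for i, c in enumerate(compound_ids)}
    smiles = {c: "C" * (1 + i % 12) for i, c in enumerate(compound_ids)}

    csv_lines = ["compound_id,inchikey,smiles,cas_number,pubchem_cid,names"]
    for i, c in enumerate(compound_ids):
        names = f"Compound {c}|cpd-{c.lower()}"
        csv_lines.append(
            f"{c},{inchikeys[c]},{smiles[c]},{cas[c]},{cids[c]},{names}"
        )
    compounds_csv = out_dir / "compounds.csv"
    compounds_csv.write_text("\n".join(csv_lines) + "\n", encoding="utf-8")

    # plant interactions
    planted_onmap: set[tuple[str, str]] = set()
    planted_offmap: set[tuple[str, str]] = set()
    ctd_rows: list[str] = []
    chembl_rows: list[str] = []
    for i, c in enumerate(compound_ids):
        for j, g in enumerate(genes):
            if rng.random() >= spec.interaction_density:
                continue
            if rng.random() < spec.offmap_gene_fraction:
                symbol = f"OFF{g}"  # guaranteed absent from the map
                planted_offmap.add((c, symbol))
            else:
                symbol = g
                planted_onmap.add((c, symbol))
            in_ctd = rng.random() < 0.5
            if rng.random() < spec.duplicate_source_fraction:
                both = True
            else:
                both = False
            # occasional lowercase spelling exercises symbol normalization
            spelled = symbol.lower() if rng.random() < 0.2 else symbol
            if in_ctd or both:
                ctd_rows.append(
                    f"Compound {c}\t{cas[c]}\t{spelled}\taffects^binding"
                )
            if (not in_ctd) or both:
                key = inchikeys[c] if i % 2 == 0 else str(cids[c])
                chembl_rows.append(f"{key}\t{spelled}\ttarget of {spelled}")

    # planted rows the parser must skip (empty gene / unclassifiable key)
    for k in range(spec.n_malformed_rows):
        if k % 2 == 0:
            ctd_rows.append(f"Broken\t{cas[compound_ids[0]]}\t\taffects")
        else:
            chembl_rows.append(f"not-a-key-{k}\tGENE{k}\t")
    # planted rows that parse but resolve to no compound
    for k in range(spec.n_unresolved_rows):
        if k % 2 == 0:
            ctd_rows.append(f"Ghost\t{9000000 - k}-99-9\tG{0:0{gwidth}d}\taffects")
        else:
            chembl_rows.append(f"{999000 + k}\tG{0:0{gwidth}d}\tghost target")

    ctd_tsv = out_dir / "ctd.tsv"
    ctd_tsv.write_text(
        "# synthetic CTD-style export\n"
        "ChemicalName\tCasRN\tGeneSymbol\tInteractionActions\n"
        + "".join(line + "\n" for line in ctd_rows),
        encoding="utf-8",
    )
    chembl_tsv = out_dir / "chembl.tsv"
    chembl_tsv.write_text(
        "compound_key\tgene_symbol\ttarget_name\n"
        + "".join(line + "\n" for line in chembl_rows),
        encoding="utf-8",
    )

    # SBML map: one PROTEIN species per gene plus two small molecules
    parts = [_SBML_HEADER.format(model_id="synthetic_map")]
    for j, g in enumerate(genes):
        parts.append(
            _SBML_SPECIES_CLASSED.format(sid=f"s{j}", name=g, cls="PROTEIN")
        )
    parts.append(_SBML_SPECIES_PLAIN.format(sid="m0", name="ATP"))
    parts.append(_SBML_SPECIES_PLAIN.format(sid="m1", name="GSH"))
    parts.append(_SBML_FOOTER)
    map_sbml = out_dir / "map.xml"
    map_sbml.write_text("".join(parts), encoding="utf-8")

    manifest = FixtureManifest(
        out_dir=out_dir,
        compounds_csv=compounds_csv,
        ctd_tsv=ctd_tsv,
        chembl_tsv=chembl_tsv,
        map_sbml=map_sbml,
        planted_onmap=planted_onmap,
        planted_offmap=planted_offmap,
        n_malformed_rows=spec.n_malformed_rows,
        n_unresolved_rows=spec.n_unresolved_rows,
    )
    truth = {
        "onmap": sorted(list(p) for p in planted_onmap),
        "offmap": sorted(list(p) for p in planted_offmap),
        "n_malformed_rows": spec.n_malformed_rows,
        "n_unresolved_rows": spec.n_unresolved_rows,
    }
    (out_dir / "planted_truth.json").write_text(
        json.dumps(truth, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest


def demo_fixture_dir() -> Path:
    """Directory of the small demo dataset shipped with the package.

    The demo contains a handful of well-known compounds (including curcumin,
    CAS 458-37-7) and a toy disease-map excerpt whose species include CFTR,
    so the documented worked example runs out of the box.
    """
    return Path(str(resources.files("compoundmap").joinpath("data", "demo")))
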