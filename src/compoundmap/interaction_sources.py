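"""Chemical-gene interaction ingest from two TSV dialects.

Two offline export dialects are supported:

* CTD-style: rows keyed by CAS registry number (columns ``CasRN``,
  ``GeneSymbol``; optional ``ChemicalName``, ``InteractionActions``), the
  shape of a Comparative Toxicogenomics Database chemical-gene export.
* ChEMBL-style: rows keyed by InChIKey or PubChem CID (columns
  ``compound_key``, ``gene_symbol``; optional ``target_name``), representing
  the end product of a protein-target-to-gene-symbol lookup.

Parsing keeps raw values verbatim; resolution maps compound keys into a
:class:`~compoundmap.compound_db.CompoundCollection` and normalizes gene
symbols to uppercase trimmed form.  Unresolvable rows are reported, never
silently dropped, so row counts always reconcile:
``input = skipped + resolved + unresolved``.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .compound_db import INCHIKEY_RE, CompoundCollection
from .errors import FormatError, InputError

logger = logging.getLogger(__name__)

Source = Literal["CTD", "CHEMBL", "CUSTOM"]

_ALL_DIGITS_RE = re.compile(r"^\d+$")


@dataclass(frozen=True)
class RawInteractionRow:
    """One line of an interaction table, values verbatim from the file."""

    compound_key: str
    key_kind: Literal["cas", "inchikey", "cid"]
    gene_symbol: str
    evidence: str | None = None


@dataclass
class ParseResult:
    """Rows plus bookkeeping so counts reconcile with the input file."""

    rows: list[RawInteractionRow]
    n_input: int
    n_skipped: int

    def __post_init__(self) -> None:
        assert self.n_input == len(self.rows) + self.n_skipped


@dataclass(frozen=True, order=True)
class InteractionRecord:
    """One normalized compound-gene assertion with its source tag."""

    compound_id: str
    gene_symbol: str
    source: Source = "CUSTOM"
    evidence: str | None = None

    def __post_init__(self) -> None:
        assert self.gene_symbol == self.gene_symbol.strip().upper() != ""

    @property
    def pair(self) -> tuple[str, str]:
        return (self.compound_id, self.gene_symbol)


@dataclass
class UnresolvedReport:
    """Interaction rows whose compound key had no match in the collection."""

    entries: list[tuple[str, str]] = field(default_factory=list)  # (key, reason)

    def add(self, key: str, reason: str) -> None:
        self.entries.append((key, reason))

    def __len__(self) -> int:
        return len(self.entries)


def _read_tsv(path: Path, required: Sequence[str]) -> tuple[list[str], list[dict]]:
    if not path.exists():
        raise InputError(f"interaction table not found: {path}")
    with path.open(newline="", encoding="utf-8") as fh:
        lines = (line for line in fh if not line.startswith("#"))
        reader = csv.DictReader(lines, delimiter="\t")
        header = reader.fieldnames or []
        for col in required:
            if col not in header:
                raise FormatError(f"{path}: missing required column '{col}'")
        return header, list(reader)


def parse_ctd_table(path: str | Path) -> ParseResult:
    """Parse a CTD-style TSV keyed by CAS registry number.

    Rows with an empty ``CasRN`` or ``GeneSymbol`` are counted and logged,
    not returned.  ``InteractionActions`` is carried verbatim into the row's
    evidence field; no interaction-type filter is applied.
    """
    path = Path(path)
    _, rows = _read_tsv(path, required=("CasRN", "GeneSymbol"))
    out: list[RawInteractionRow] = []
    n_skipped = 0
    for row in rows:
        cas = (row.get("CasRN") or "").strip()
        gene = (row.get("GeneSymbol") or "").strip()
        if not cas or not gene:
            n_skipped += 1
            logger.info("%s: skipped row with empty CasRN/GeneSymbol: %r", path, row)
            continue
        out.append(
            RawInteractionRow(
                compound_key=cas,
                key_kind="cas",
                gene_symbol=row["GeneSymbol"],  # verbatim; normalization deferred
                evidence=(row.get("InteractionActions") or None),
            )
        )
    return ParseResult(rows=out, n_input=len(rows), n_skipped=n_skipped)


def classify_compound_key(key: str) -> Literal["cid", "inchikey"] | None:
    """Classify a ChEMBL-dialect compound key: all digits means PubChem CID,
    InChIKey-shaped means InChIKey, anything else is unrecognized."""
    key = key.strip()
    if _ALL_DIGITS_RE.match(key):
        return "cid"
    if INCHIKEY_RE.match(key):
        return "inchikey"
    return None


def parse_chembl_table(path: str | Path) -> ParseResult:
    """Parse a ChEMBL-style TSV keyed by InChIKey or PubChem CID.

    Keys that are neither all-digits nor InChIKey-shaped are skipped and
    logged, as are rows missing a key or gene symbol.
    """
    path = Path(path)
    _, rows = _read_tsv(path, required=("compound_key", "gene_symbol"))
    out: list[RawInteractionRow] = []
    n_skipped = 0
    for row in rows:
        key = (row.get("compound_key") or "").strip()
        gene = (row.get("gene_symbol") or "").strip()
        kind = classify_compound_key(key) if key else None
        if not key or not gene or kind is None:
            n_skipped += 1
            logger.info("%s: skipped row (bad key or empty gene): %r", path, row)
            continue
        out.append(
            RawInteractionRow(
                compound_key=key,
                key_kind=kind,
                gene_symbol=row["gene_symbol"],
                evidence=(row.get("target_name") or None),
            )
        )
    return ParseResult(rows=out, n_input=len(rows), n_skipped=n_skipped)


def resolve_interactions(
    rows: Iterable[RawInteractionRow],
    collection: CompoundCollection,
    source: Source,
) -> tuple[list[InteractionRecord], UnresolvedReport]:
    """Map raw rows' compound keys into the collection.

    CAS keys (CTD dialect) and InChIKey/CID keys (ChEMBL dialect) are looked
    up in the collection's qualified identifier index.  Gene symbols are
    uppercased and trimmed here.  Rows whose key resolves to no compound are
    returned in the :class:`UnresolvedReport` — resolution failure is data,
    not an error.
    """
    records: list[InteractionRecord] = []
    report = UnresolvedReport()
    for row in rows:
        compound_id = collection.lookup_identifier(row.key_kind, row.compound_key)
        if compound_id is None:
            report.add(row.compound_key, f"no compound with {row.key_kind} key")
            continue
        records.append(
            InteractionRecord(
                compound_id=compound_id,
                gene_symbol=row.gene_symbol.strip().upper(),
                source=source,
                evidence=row.evidence,
            )
        )
    return records, report


def merge_interactions(
    *lists: Sequence[InteractionRecord],
) -> list[InteractionRecord]:
    """Deduplicate interaction lists on (compound_id, gene_symbol).

    When the same pair is asserted by several sources, the source tag of the
    first occurrence wins and all distinct source names and evidence strings
    are concatenated into the merged record's evidence field.  Output is
    sorted by (compound_id, gene_symbol); merging is idempotent.
    """
    merged: dict[tuple[str, str], InteractionRecord] = {}
    sources_seen: dict[tuple[str, str], list[str]] = {}
    evidence_seen: dict[tuple[str, str], list[str]] = {}

    for lst in lists:
        for rec in lst:
            key = rec.pair
            if key not in merged:
                merged[key] = rec
                sources_seen[key] = [rec.source]
                evidence_seen[key] = [rec.evidence] if rec.evidence else []
            else:
                if rec.source not in sources_seen[key]:
                    sources_seen[key].append(rec.source)
                if rec.evidence and rec.evidence not in evidence_seen[key]:
                    evidence_seen[key].append(rec.evidence)

    out: list[InteractionRecord] = []
    for key in sorted(merged):
        rec = merged[key]
        parts = list(evidence_seen[key])
        if len(sources_seen[key]) > 1:
            parts.append("sources: " + "+".join(sources_seen[key]))
        evidence = "; ".join(parts) if parts else None
        out.append(
            InteractionRecord(
                compound_id=rec.compound_id,
                gene_symbol=rec.gene_symbol,
                source=rec.source,
                evidence=evidence,
            )
        )
    return out
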