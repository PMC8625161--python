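"""Custom compound-collection ingest and search.

The collection plays the role of an application-specific candidate-therapeutics
database: each record carries an opaque primary key plus whichever standard
chemical identifiers are known (InChIKey, SMILES, CAS registry number,
PubChem CID) and an ordered synonym list.  Compounds synthesized for a single
study frequently lack one or more of these identifiers, so malformed optional
identifiers degrade to absent rather than rejecting the row.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from .errors import FormatError, InputError, ValidationError

logger = logging.getLogger(__name__)

#: Standard InChIKey shape: 14 uppercase letters, hyphen, 10, hyphen, 1.
INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")

#: CAS registry number: 2-7 digits, hyphen, 2 digits, hyphen, 1 check digit.
CAS_RE = re.compile(r"^\d{2,7}-\d{2}-\d$")

CSV_COLUMNS = ["compound_id", "inchikey", "smiles", "cas_number", "pubchem_cid", "names"]


def _norm_name(name: str) -> str:
    """Case-folded, whitespace-trimmed synonym key."""
    return name.strip().casefold()


@dataclass(frozen=True)
class CompoundRecord:
    """One entry of the compound collection.

    ``names`` is never empty; its first element is the preferred display name.
    Optional identifiers are ``None`` when unknown or malformed in the source.
    """

    compound_id: str
    names: tuple[str, ...]
    inchikey: str | None = None
    smiles: str | None = None
    cas_number: str | None = None
    pubchem_cid: int | None = None

    @property
    def display_name(self) -> str:
        return self.names[0]

    def to_dict(self) -> dict:
        return {
            "compound_id": self.compound_id,
            "inchikey": self.inchikey,
            "smiles": self.smiles,
            "cas_number": self.cas_number,
            "pubchem_cid": self.pubchem_cid,
            "names": list(self.names),
        }


@dataclass
class CompoundCollection:
    """Record list plus the two lookup indices used by search and resolution.

    ``synonym_index`` maps normalized names to compound_id lists;
    ``id_index`` maps identifier-kind-qualified keys, e.g. ``("cas",
    "458-37-7")``, to a single compound_id.
    """

    records: list[CompoundRecord]
    synonym_index: dict[str, list[str]] = field(default_factory=dict)
    id_index: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.synonym_index and not self.id_index:
            self._build_indices()

    def _build_indices(self) -> None:
        for rec in self.records:
            for name in rec.names:
                self.synonym_index.setdefault(_norm_name(name), []).append(
                    rec.compound_id
                )
            self._index_id("compound_id", rec.compound_id, rec.compound_id)
            if rec.inchikey:
                self._index_id("inchikey", rec.inchikey, rec.compound_id)
            if rec.cas_number:
                self._index_id("cas", rec.cas_number, rec.compound_id)
            if rec.pubchem_cid is not None:
                self._index_id("cid", str(rec.pubchem_cid), rec.compound_id)

    def _index_id(self, kind: str, key: str, compound_id: str) -> None:
        existing = self.id_index.setdefault((kind, key), compound_id)
        if existing != compound_id:
            logger.warning(
                "identifier collision: %s %r already maps to %s; keeping first "
                "(ignoring %s)", kind, key, existing, compound_id,
            )

    def get(self, compound_id: str) -> CompoundRecord | None:
        cid = self.id_index.get(("compound_id", compound_id))
        if cid is None:
            return None
        return self._by_id[cid]

    @property
    def _by_id(self) -> dict[str, CompoundRecord]:
        # small collections: rebuild lazily, cache on the instance
        cache = getattr(self, "_by_id_cache", None)
        if cache is None:
            cache = {r.compound_id: r for r in self.records}
            object.__setattr__(self, "_by_id_cache", cache)
        return cache

    def lookup_identifier(self, kind: str, key: str) -> str | None:
        """Resolve one qualified identifier to a compound_id, or None."""
        return self.id_index.get((kind, key))

    def __len__(self) -> int:
        return len(self.records)


def _clean_optional(
    compound_id: str, kind: str, value: str | None, pattern: re.Pattern | None
) -> str | None:
    """Validate an optional identifier; malformed values become None + warning."""
    if value is None:
        return None
    value = value.strip()
    if not value:
        return None
    if pattern is not None and not pattern.match(value):
        logger.warning(
            "compound %s: malformed %s %r dropped", compound_id, kind, value
        )
        return None
    return value


def _record_from_raw(raw: dict) -> CompoundRecord:
    compound_id = str(raw.get("compound_id") or "").strip()
    if not compound_id:
        raise ValidationError("record with empty compound_id")

    names_field = raw.get("names")
    if isinstance(names_field, str):
        names = [n.strip() for n in names_field.split("|") if n.strip()]
    elif names_field:
        names = [str(n).strip() for n in names_field if str(n).strip()]
    else:
        names = []
    if not names:
        # a record must be displayable; fall back to its id
        names = [compound_id]

    inchikey = _clean_optional(compound_id, "inchikey", raw.get("inchikey"), INCHIKEY_RE)
    cas = _clean_optional(compound_id, "cas_number", raw.get("cas_number"), CAS_RE)
    smiles = _clean_optional(compound_id, "smiles", raw.get("smiles"), None)

    cid_raw = raw.get("pubchem_cid")
    pubchem_cid: int | None = None
    if cid_raw is not None and str(cid_raw).strip():
        try:
            pubchem_cid = int(str(cid_raw).strip())
            if pubchem_cid <= 0:
                raise ValueError
        except ValueError:
            logger.warning(
                "compound %s: malformed pubchem_cid %r dropped", compound_id, cid_raw
            )
            pubchem_cid = None

    return CompoundRecord(
        compound_id=compound_id,
        names=tuple(names),
        inchikey=inchikey,
        smiles=smiles,
        cas_number=cas,
        pubchem_cid=pubchem_cid,
    )


def _validate_collection(records: list[CompoundRecord]) -> None:
    if not records:
        raise ValidationError("compound collection is empty")
    seen: set[str] = set()
    for rec in records:
        if rec.compound_id in seen:
            raise ValidationError(f"duplicate compound_id {rec.compound_id!r}")
        seen.add(rec.compound_id)


def load_compound_db(
    path: str | Path, format: Literal["csv", "json"] | None = None
) -> CompoundCollection:
    """Read a compound collection from CSV or JSON and build its indices.

    CSV dialect: UTF-8, header row required, comma-separated; the ``names``
    cell is a pipe-separated synonym list.  JSON: an array of objects with the
    same keys and ``names`` as an array.  ``format`` is inferred from the file
    extension when not given.

    Raises
    ------
    InputError
        if the file does not exist.
    FormatError
        if it cannot be parsed in the declared format or lacks ``compound_id``.
    ValidationError
        on duplicate compound_id or an empty collection.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"compound database file not found: {path}")
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"

    if format == "json":
        try:
            raw_rows = json.loads(path.read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON: {exc}") from exc
        if not isinstance(raw_rows, list):
            raise FormatError(f"{path}: expected a JSON array of compound objects")
        for row in raw_rows:
            if "compound_id" not in row:
                raise FormatError(f"{path}: object missing required key 'compound_id'")
    else:
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "compound_id" not in reader.fieldnames:
                raise FormatError(f"{path}: missing required column 'compound_id'")
            raw_rows = list(reader)

    records = [_record_from_raw(row) for row in raw_rows]
    _validate_collection(records)
    return CompoundCollection(records=records)


def save_compound_db(collection: CompoundCollection, path: str | Path) -> None:
    """Serialize a collection to the JSON dialect (round-trips with load)."""
    path = Path(path)
    path.write_text(
        json.dumps([r.to_dict() for r in collection.records], indent=2, sort_keys=True)
        + "\n",
        encoding="utf-8",
    )


def find_compounds(
    query: str,
    collection: CompoundCollection,
    mode: Literal["synonym", "exact_id"] = "synonym",
    contains: bool = False,
) -> list[CompoundRecord]:
    """Search the collection by synonym or by exact identifier.

    ``synonym`` mode matches the case-folded, trimmed query against every
    synonym of every record (exact token match; ``contains=True`` switches to
    substring matching).  ``exact_id`` mode compares the query verbatim
    against compound_id, InChIKey, CAS number, SMILES, and the string form of
    the PubChem CID.  Results are ordered by ascending compound_id; no match
    is an empty list, not an error.
    """
    query = query.strip()
    if not query:
        raise InputError("empty search query")

    hits: set[str] = set()
    if mode == "synonym":
        key = _norm_name(query)
        if contains:
            for name_key, ids in collection.synonym_index.items():
                if key in name_key:
                    hits.update(ids)
        else:
            hits.update(collection.synonym_index.get(key, []))
    elif mode == "exact_id":
        for kind in ("compound_id", "inchikey", "cas", "cid"):
            cid = collection.id_index.get((kind, query))
            if cid is not None:
                hits.add(cid)
        for rec in collection.records:  # SMILES: verbatim string equality
            if rec.smiles is not None and rec.smiles == query:
                hits.add(rec.compound_id)
    else:
        raise InputError(f"unknown search mode {mode!r}")

    by_id = {r.compound_id: r for r in collection.records}
    return [by_id[cid] for cid in sorted(hits)]


def iter_names(records: Iterable[CompoundRecord]) -> Iterable[str]:
    for rec in records:
        yield from rec.names
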