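"""Build, write, and read the paired compound/gene link index.

The link index is the tool's central artifact: a forward mapping
(compound_id -> target gene symbols present in the map) and its transpose
(map gene symbol -> compound_ids), materialized as two JSON files,
``compound2genes.json`` and ``gene2compounds.json``.  Keeping both directions
pre-computed makes compound-target overlay and reverse target search O(1)
lookups for a consumer.

Interactions whose gene symbol does not occur in the map are excluded from
both directions at build time and counted; compounds with zero map-covered
targets are omitted from the forward mapping to keep the files small.  The
reverse mapping keeps one key per map gene-like symbol, with an empty list
when no compound targets it, so coverage is computable from the reverse file
alone.

The header block carries provenance (map checksum, source table names, build
timestamp, tool version) so a stale index is detectable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from . import __version__
from .disease_map import EntityIndex, symbols_in_map
from .errors import FormatError, IntegrityError, InputError, ValidationError
from .interaction_sources import InteractionRecord

logger = logging.getLogger(__name__)

FORWARD_FILENAME = "compound2genes.json"
REVERSE_FILENAME = "gene2compounds.json"


@dataclass
class LinkIndex:
    """Paired forward/reverse mappings plus a provenance header.

    Invariants: ``g in forward[c]`` iff ``c in reverse[g]``; every reverse key
    belongs to the map's gene-like symbol universe; all lists are sorted and
    duplicate-free.
    """

    forward: dict[str, list[str]]
    reverse: dict[str, list[str]]
    header: dict = field(default_factory=dict)
    n_dropped: int = 0

    @property
    def n_pairs(self) -> int:
        return sum(len(v) for v in self.forward.values())

    def pairs(self) -> set[tuple[str, str]]:
        """The set of (compound_id, gene_symbol) links in the index."""
        return {(c, g) for c, genes in self.forward.items() for g in genes}


def file_checksum(path: str | Path) -> str:
    return "sha256:" + hashlib.sha256(Path(path).read_bytes()).hexdigest()


def build_index(
    interactions: Iterable[InteractionRecord],
    index: EntityIndex,
    gene_like_only: bool = True,
    map_checksum: str | None = None,
    source_tables: Sequence[str] = (),
    timestamp: str | None = None,
) -> LinkIndex:
    """Intersect interactions with the map's symbol universe.

    ``timestamp`` pins the header build time (ISO-8601 string); pass a fixed
    value to make the written files byte-reproducible.

    Raises a validation error when the map's symbol universe is empty.
    """
    universe = set(symbols_in_map(index, gene_like_only=gene_like_only))
    if not universe:
        raise ValidationError("disease map has no gene-like symbols to link against")

    forward: dict[str, set[str]] = {}
    n_dropped = 0
    seen_pairs: set[tuple[str, str]] = set()
    for rec in interactions:
        if rec.pair in seen_pairs:
            continue
        seen_pairs.add(rec.pair)
        if rec.gene_symbol not in universe:
            n_dropped += 1
            continue
        forward.setdefault(rec.compound_id, set()).add(rec.gene_symbol)

    fwd = {c: sorted(genes) for c, genes in forward.items()}
    rev: dict[str, list[str]] = {g: [] for g in universe}
    for c, genes in fwd.items():
        for g in genes:
            rev[g].append(c)
    rev = {g: sorted(cs) for g, cs in rev.items()}

    header = {
        "format": "compoundmap-link-index",
        "version": __version__,
        "map_checksum": map_checksum,
        "source_tables": sorted(source_tables),
        "built_at": timestamp,
        "gene_like_only": gene_like_only,
        "n_dropped_offmap": n_dropped,
    }
    return LinkIndex(forward=fwd, reverse=rev, header=header, n_dropped=n_dropped)


def _dump(payload: dict, path: Path) -> None:
    path.write_text(
        json.dumps(payload, indent=2, sort_keys=True, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )


def write_index(link: LinkIndex, out_dir: str | Path) -> tuple[Path, Path]:
    """Write the two JSON index files; returns (forward_path, reverse_path).

    Output is UTF-8 with sorted keys and 2-space indent, so identical index
    content (with a pinned header timestamp) yields byte-identical files.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        fwd_path = out_dir / FORWARD_FILENAME
        rev_path = out_dir / REVERSE_FILENAME
        _dump({"header": link.header, "compounds": link.forward}, fwd_path)
        _dump({"header": link.header, "genes": link.reverse}, rev_path)
    except OSError as exc:
        raise InputError(f"cannot write index to {out_dir}: {exc}") from exc
    return fwd_path, rev_path


def _check_mapping(obj: dict, key: str, path: Path) -> dict[str, list[str]]:
    """Structural schema check for one index file (shipped schema documents
    describe the same shape)."""
    if not isinstance(obj, dict):
        raise FormatError(f"{path}: top level must be a JSON object")
    for required in ("header", key):
        if required not in obj:
            raise FormatError(f"{path}: missing required key '{required}'")
    mapping = obj[key]
    if not isinstance(mapping, dict):
        raise FormatError(f"{path}: '{key}' must be an object")
    out: dict[str, list[str]] = {}
    for k, v in mapping.items():
        if not isinstance(v, list) or not all(isinstance(x, str) for x in v):
            raise FormatError(f"{path}: '{key}.{k}' must be a list of strings")
        norm = sorted(set(v))
        if norm != v:
            logger.warning("%s: '%s.%s' not sorted/deduplicated; normalized", path, key, k)
        out[k] = norm
    return out


def verify_transpose(
    forward: dict[str, list[str]], reverse: dict[str, list[str]]
) -> tuple[str, str] | None:
    """Return one witness (compound, gene) pair violating transpose
    consistency, or None when the two mappings agree."""
    fwd_pairs = {(c, g) for c, genes in forward.items() for g in genes}
    rev_pairs = {(c, g) for g, comps in reverse.items() for c in comps}
    diff = fwd_pairs.symmetric_difference(rev_pairs)
    if diff:
        return min(diff)
    return None


def read_index(path: str | Path) -> LinkIndex:
    """Load a link index from a directory (or either of its two files).

    Schema violations raise a format error naming the offending key; a
    forward/reverse contradiction raises an integrity error naming one
    witness pair.  Unsorted lists are normalized with a warning.
    """
    path = Path(path)
    if path.is_dir():
        fwd_path, rev_path = path / FORWARD_FILENAME, path / REVERSE_FILENAME
    else:
        fwd_path, rev_path = path.parent / FORWARD_FILENAME, path.parent / REVERSE_FILENAME
    for p in (fwd_path, rev_path):
        if not p.exists():
            raise InputError(f"index file not found: {p}")

    try:
        fwd_obj = json.loads(fwd_path.read_text(encoding="utf-8"))
        rev_obj = json.loads(rev_path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"invalid JSON in index file: {exc}") from exc

    forward = _check_mapping(fwd_obj, "compounds", fwd_path)
    reverse = _check_mapping(rev_obj, "genes", rev_path)

    witness = verify_transpose(forward, reverse)
    if witness is not None:
        raise IntegrityError(
            f"forward/reverse index files disagree on pair {witness!r}"
        )

    header = fwd_obj.get("header") or {}
    return LinkIndex(
        forward=forward,
        reverse=reverse,
        header=header,
        n_dropped=int(header.get("n_dropped_offmap") or 0),
    )
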