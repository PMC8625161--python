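"""Queries over a link index + entity index.

Three query families mirror the tool's use cases: compound target overlay
(one compound, or the intersection of two), reverse target search (which
compounds hit a selected map entity), and database-map coverage.

Symbols vs entities: the index stores gene *symbols*; one symbol may be
realized by several map entities (e.g. the same protein in two compartments).
Queries therefore fan a symbol out to every matching gene-like entity, and
highlight counts are per-entity, matching how a map viewer pins species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .disease_map import EntityIndex
from .errors import InputError
from .index_builder import LinkIndex


@dataclass
class TargetHighlightSet:
    """The map entities a query would highlight."""

    query_description: str
    symbols: list[str]
    entity_ids: list[str]

    @property
    def n_targets(self) -> int:
        return len(self.entity_ids)

    def to_dict(self) -> dict:
        return {
            "query": self.query_description,
            "symbols": self.symbols,
            "entity_ids": self.entity_ids,
            "n_symbols": len(self.symbols),
            "n_targets": self.n_targets,
        }


@dataclass
class CoverageReport:
    """How much of the map's gene-like symbol universe the collection hits."""

    n_gene_entities: int
    n_covered: int
    n_compounds_mapped: int
    highlight: TargetHighlightSet = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def fraction(self) -> float:
        return self.n_covered / self.n_gene_entities if self.n_gene_entities else 0.0

    def to_dict(self) -> dict:
        return {
            "n_gene_entities": self.n_gene_entities,
            "n_covered": self.n_covered,
            "fraction": self.fraction,
            "n_compounds_mapped": self.n_compounds_mapped,
            "highlight": self.highlight.to_dict() if self.highlight else None,
        }


def _fan_out(symbols: list[str], index: EntityIndex) -> list[str]:
    ids: set[str] = set()
    for sym in symbols:
        ids.update(index.entities_for_symbol(sym, gene_like_only=True))
    return sorted(ids)


def _highlight(description: str, symbols: set[str], index: EntityIndex) -> TargetHighlightSet:
    ordered = sorted(symbols)
    return TargetHighlightSet(
        query_description=description,
        symbols=ordered,
        entity_ids=_fan_out(ordered, index),
    )


def targets_of(
    compound_id: str, link: LinkIndex, index: EntityIndex
) -> TargetHighlightSet:
    """Map targets of one compound.

    A compound absent from the forward index (unknown, or with no map-covered
    targets) yields an empty set, mirroring a search that returns nothing.
    """
    symbols = set(link.forward.get(compound_id, []))
    return _highlight(f"targets of {compound_id}", symbols, index)


def common_targets(
    compound_a: str, compound_b: str, link: LinkIndex, index: EntityIndex
) -> TargetHighlightSet:
    """Targets shared by two compounds (symbol-level set intersection);
    symmetric in its arguments."""
    shared = set(link.forward.get(compound_a, [])) & set(link.forward.get(compound_b, []))
    return _highlight(f"common targets of {compound_a} and {compound_b}", shared, index)


def intersect_targets(
    compound_ids: list[str], link: LinkIndex, index: EntityIndex
) -> TargetHighlightSet:
    """Iterated intersection over n compounds; generalizes the pairwise compare."""
    if not compound_ids:
        raise InputError("no compounds given")
    shared = set(link.forward.get(compound_ids[0], []))
    for cid in compound_ids[1:]:
        shared &= set(link.forward.get(cid, []))
    return _highlight("common targets of " + ", ".join(compound_ids), shared, index)


def compounds_for(
    selection: str, link: LinkIndex, index: EntityIndex
) -> list[str]:
    """Reverse target search: compounds interacting with a selected entity.

    ``selection`` may be a map entity id (translated to its display symbol)
    or a gene symbol (case-insensitive).  An entity whose symbol was excluded
    from the index build (non-gene-like, under the default build flag) yields
    an empty list.  A selection matching neither an entity id nor a known
    symbol is an input error naming it.
    """
    entity = index.get(selection)
    if entity is not None:
        symbol = entity.symbol
    else:
        symbol = selection.strip().upper()
        if symbol not in index.by_symbol and symbol not in link.reverse:
            raise InputError(f"unknown map entity or symbol: {selection!r}")
    return sorted(link.reverse.get(symbol, []))


def coverage(link: LinkIndex, index: EntityIndex) -> CoverageReport:
    """Database-map coverage: the fraction of map gene-like symbols targeted
    by at least one compound, plus the full highlight set for display."""
    covered = {g for g, comps in link.reverse.items() if comps}
    return CoverageReport(
        n_gene_entities=len(link.reverse),
        n_covered=len(covered),
        n_compounds_mapped=len(link.forward),
        highlight=_highlight("all targets of all compounds", covered, index),
    )
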