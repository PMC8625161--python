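"""Entity extraction from an SBML disease map.

A disease map is a curated network of molecular interactions encoded in SBML
(level 2 or 3), often with CellDesigner extension annotations carrying the
species class (PROTEIN, GENE, RNA, ...).  This module extracts one entity per
SBML species and builds a name-normalized index so interaction gene symbols
can be matched against the map by uppercase exact name/alias equality.

Parsing is namespace-tolerant: elements are matched on their local names, so
maps mixing CellDesigner namespace versions load without special-casing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

from lxml import etree

from .errors import FormatError, InputError, ValidationError

EntityClass = Literal["GENE", "PROTEIN", "RNA", "OTHER"]

#: CellDesigner class strings mapped onto the entity-class enum.  Complexes
#: and small molecules (and anything unrecognized) collapse to OTHER.
_CLASS_MAP: dict[str, EntityClass] = {
    "PROTEIN": "PROTEIN",
    "GENE": "GENE",
    "RNA": "RNA",
    "ANTISENSE_RNA": "RNA",
}

GENE_LIKE: frozenset[EntityClass] = frozenset({"GENE", "PROTEIN", "RNA"})


@dataclass(frozen=True)
class MapEntity:
    """One named species of the disease map."""

    entity_id: str
    display_name: str
    entity_class: EntityClass = "OTHER"
    aliases: tuple[str, ...] = ()
    compartment: str | None = None

    @property
    def symbol(self) -> str:
        """Uppercase matching form of the display name."""
        return self.display_name.strip().upper()


@dataclass
class EntityIndex:
    """Entity list plus the uppercase-name lookup used for symbol matching."""

    entities: list[MapEntity]
    by_symbol: dict[str, list[str]] = field(default_factory=dict)
    gene_like_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.by_symbol and not self.gene_like_ids:
            for ent in self.entities:
                for name in (ent.display_name, *ent.aliases):
                    key = name.strip().upper()
                    if not key:
                        continue
                    ids = self.by_symbol.setdefault(key, [])
                    if ent.entity_id not in ids:
                        ids.append(ent.entity_id)
                if ent.entity_class in GENE_LIKE:
                    self.gene_like_ids.add(ent.entity_id)

    def get(self, entity_id: str) -> MapEntity | None:
        for ent in self.entities:
            if ent.entity_id == entity_id:
                return ent
        return None

    def entities_for_symbol(
        self, symbol: str, gene_like_only: bool = True
    ) -> list[str]:
        """Entity ids realizing one uppercase symbol, sorted."""
        ids = self.by_symbol.get(symbol.strip().upper(), [])
        if gene_like_only:
            ids = [i for i in ids if i in self.gene_like_ids]
        return sorted(ids)


def _localname(el: etree._Element) -> str:
    return etree.QName(el).localname


def _species_class(species: etree._Element) -> EntityClass:
    """Read the CellDesigner class annotation of one species, if any."""
    for el in species.iter():
        if _localname(el) == "class" and el.text:
            return _CLASS_MAP.get(el.text.strip().upper(), "OTHER")
    return "OTHER"


def parse_disease_map(path: str | Path) -> EntityIndex:
    """Parse an SBML file into an :class:`EntityIndex`.

    One :class:`MapEntity` per SBML species.  The entity class is read from a
    CellDesigner ``class`` annotation when present; plain species default to
    OTHER.  Raises a format error with the line number on malformed XML and a
    validation error when the map declares no species.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"disease map file not found: {path}")
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"{path}: XML parse failure at line {exc.lineno}: {exc.msg}") from exc

    entities: list[MapEntity] = []
    seen_ids: set[str] = set()
    for el in tree.getroot().iter():
        if _localname(el) != "species":
            continue
        # skip CellDesigner's own <celldesigner:species> bookkeeping elements
        parent = el.getparent()
        if parent is None or _localname(parent) != "listOfSpecies":
            continue
        sid = el.get("id") or ""
        name = (el.get("name") or sid).strip()
        if not sid or sid in seen_ids:
            continue
        seen_ids.add(sid)
        entities.append(
            MapEntity(
                entity_id=sid,
                display_name=name if name else sid,
                entity_class=_species_class(el),
                compartment=el.get("compartment"),
            )
        )

    if not entities:
        raise ValidationError(f"{path}: disease map contains no species")
    return EntityIndex(entities=entities)


def symbols_in_map(index: EntityIndex, gene_like_only: bool = True) -> list[str]:
    """Deduplicated, sorted, uppercased name universe of the map.

    With ``gene_like_only`` (the default) only names of GENE/PROTEIN/RNA
    entities are returned; metabolites and complexes are excluded.
    """
    symbols: set[str] = set()
    for sym, ids in index.by_symbol.items():
        if gene_like_only and not any(i in index.gene_like_ids for i in ids):
            continue
        symbols.add(sym)
    return sorted(symbols)
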