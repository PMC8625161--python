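"""End-to-end build orchestration: load -> parse -> resolve -> merge -> build.

Thin glue shared by the CLI ``build`` subcommand and programmatic callers;
all the real work happens in the per-stage modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .compound_db import load_compound_db
from .disease_map import parse_disease_map
from .index_builder import LinkIndex, build_index, file_checksum, write_index
from .interaction_sources import (
    merge_interactions,
    parse_chembl_table,
    parse_ctd_table,
    resolve_interactions,
)
from .query_engine import coverage


@dataclass
class BuildSummary:
    """Counts accumulated across one build run."""

    n_compounds: int = 0
    n_rows_input: int = 0
    n_rows_skipped: int = 0
    n_rows_unresolved: int = 0
    n_rows_resolved: int = 0
    n_interactions_merged: int = 0
    n_dropped_offmap: int = 0
    n_map_entities: int = 0
    coverage_fraction: float = 0.0
    unresolved: list[tuple[str, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "unresolved"}
        d["n_unresolved_keys"] = len(self.unresolved)
        return d


def run_build(
    compounds_path: str | Path,
    map_path: str | Path,
    ctd_paths: Sequence[str | Path] = (),
    chembl_paths: Sequence[str | Path] = (),
    out_dir: str | Path | None = None,
    gene_like_only: bool = True,
    timestamp: str | None = None,
) -> tuple[LinkIndex, BuildSummary]:
    """Run the whole pipeline; write the index files when ``out_dir`` is set."""
    collection = load_compound_db(compounds_path)
    entity_index = parse_disease_map(map_path)

    summary = BuildSummary(
        n_compounds=len(collection), n_map_entities=len(entity_index.entities)
    )

    resolved_lists = []
    for path, parser, source in [
        *((p, parse_ctd_table, "CTD") for p in ctd_paths),
        *((p, parse_chembl_table, "CHEMBL") for p in chembl_paths),
    ]:
        result = parser(path)
        records, unresolved = resolve_interactions(result.rows, collection, source)
        summary.n_rows_input += result.n_input
        summary.n_rows_skipped += result.n_skipped
        summary.n_rows_unresolved += len(unresolved)
        summary.n_rows_resolved += len(records)
        summary.unresolved.extend(unresolved.entries)
        resolved_lists.append(records)

    merged = merge_interactions(*resolved_lists)
    summary.n_interactions_merged = len(merged)

    link = build_index(
        merged,
        entity_index,
        gene_like_only=gene_like_only,
        map_checksum=file_checksum(map_path),
        source_tables=[Path(p).name for p in (*ctd_paths, *chembl_paths)],
        timestamp=timestamp,
    )
    summary.n_dropped_offmap = link.n_dropped
    summary.coverage_fraction = coverage(link, entity_index).fraction

    if out_dir is not None:
        write_index(link, out_dir)
    return link, summary
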