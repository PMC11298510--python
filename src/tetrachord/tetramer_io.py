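"""Reading and writing the delimited-text formats of the pipeline.

Three formats are handled, all RFC 4180-style delimited text in UTF-8:

* tetramer tables in the CTD download dialect, canonical header
  ``Chemical, Chemical.ID, Gene, Gene.ID, Phenotype, Phenotype.ID,
  Disease, Disease.ID`` (underscore variants such as ``Chemical_ID`` and
  any header casing are accepted on read; the canonical form is always
  written);
* curated interaction tables with columns
  ``kind, subject_term, subject_id, object_term, object_id``;
* term hierarchies as two-column ``parent_id, child_id`` edge lists.

Unknown extra columns in a tetramer table are preserved as opaque
annotations on each record and re-emitted after the canonical eight
columns on write.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Union

import pandas as pd

from .model import (
    CuratedDatabase,
    Diagnostics,
    InteractionKind,
    InteractionRecord,
    NodeClass,
    TermHierarchy,
    TermRef,
    Tetramer,
    TetramerSet,
)

__all__ = [
    "CsvDialect",
    "MissingColumnsError",
    "read_tetramer_csv",
    "write_tetramer_csv",
    "read_interaction_table",
    "read_hierarchy_edges",
    "CANONICAL_COLUMNS",
]

CANONICAL_COLUMNS = (
    "Chemical",
    "Chemical.ID",
    "Gene",
    "Gene.ID",
    "Phenotype",
    "Phenotype.ID",
    "Disease",
    "Disease.ID",
)

_SLOT_CLASSES = (
    ("Chemical", NodeClass.CHEMICAL),
    ("Gene", NodeClass.GENE),
    ("Phenotype", NodeClass.PHENOTYPE),
    ("Disease", NodeClass.DISEASE),
)


@dataclass(frozen=True)
class CsvDialect:
    """Delimiter/quoting conventions; defaults follow RFC 4180 CSV."""

    delimiter: str = ","
    encoding: str = "utf-8"


class MissingColumnsError(ValueError):
    """The input lacks required columns; ``missing`` names them."""

    def __init__(self, missing: list[str]):
        self.missing = list(missing)
        super().__init__(
            "missing required columns: " + ", ".join(self.missing)
        )


def _canonical_header(name: str) -> str:
    """Normalize 'chemical_id' / 'Chemical.ID' / ' CHEMICAL ID' alike."""
    return name.strip().casefold().replace("_", ".").replace(" ", ".")


_CANONICAL_BY_NORM = {_canonical_header(c): c for c in CANONICAL_COLUMNS}

Source = Union[str, Path, IO[str], IO[bytes]]


def _as_dataframe(source: Source, dialect: CsvDialect) -> pd.DataFrame:
    return pd.read_csv(
        source,
        sep=dialect.delimiter,
        dtype=str,
        keep_default_na=False,
        encoding=dialect.encoding,
    )


def read_tetramer_csv(
    source: Source,
    dialect: CsvDialect = CsvDialect(),
    source_label: str = "",
) -> TetramerSet:
    """Parse a CTD-dialect tetramer CSV into a :class:`TetramerSet`.

    Each data row becomes one record; no implicit deduplication is
    performed.  Rows with an empty required cell are skipped and counted
    in the returned set's diagnostics.  A missing required column raises
    :class:`MissingColumnsError` naming the absent columns.
    """
    df = _as_dataframe(source, dialect)
    colmap: dict[str, str] = {}  # canonical -> actual column name
    extras: list[str] = []
    for col in df.columns:
        canon = _CANONICAL_BY_NORM.get(_canonical_header(col))
        if canon is not None and canon not in colmap:
            colmap[canon] = col
        else:
            extras.append(col)
    missing = [c for c in CANONICAL_COLUMNS if c not in colmap]
    if missing:
        raise MissingColumnsError(missing)

    diagnostics = Diagnostics()
    records: list[Tetramer] = []
    positions = {canon: df.columns.get_loc(col) for canon, col in colmap.items()}
    extra_pos = [(col, df.columns.get_loc(col)) for col in extras]
    for idx, row in enumerate(df.itertuples(index=False, name=None)):
        cells = {canon: str(row[pos]).strip() for canon, pos in positions.items()}
        if any(not cells[c] for c in CANONICAL_COLUMNS):
            diagnostics.skipped_rows += 1
            diagnostics.warn(
                f"row {idx + 2}: empty required cell; row skipped"
            )
            continue
        refs = {
            slot: TermRef(
                term=cells[slot],
                accession=cells[f"{slot}.ID"],
                node_class=node_class,
            )
            for slot, node_class in _SLOT_CLASSES
        }
        extra_items = tuple(
            sorted((col, str(row[pos])) for col, pos in extra_pos)
        )
        records.append(
            Tetramer(
                chemical=refs["Chemical"],
                gene=refs["Gene"],
                phenotype=refs["Phenotype"],
                disease=refs["Disease"],
                extras=extra_items,
            )
        )
    return TetramerSet(
        records=records, source_label=source_label, diagnostics=diagnostics
    )


def write_tetramer_csv(
    tset: TetramerSet,
    sink: Union[str, Path, IO[str]],
    dialect: CsvDialect = CsvDialect(),
) -> int:
    """Write a tetramer set in the canonical CTD dialect; returns rows written.

    Extra annotation columns (the union over records, sorted) follow the
    canonical eight; records lacking a key get an empty cell.
    """
    extra_cols = sorted({col for t in tset.records for col, _ in t.extras})
    header = list(CANONICAL_COLUMNS) + extra_cols

    own = isinstance(sink, (str, Path))
    handle: IO[str] = (
        open(sink, "w", newline="", encoding=dialect.encoding) if own else sink
    )
    try:
        writer = csv.writer(
            handle, delimiter=dialect.delimiter, lineterminator="\n"
        )
        writer.writerow(header)
        n = 0
        for t in tset.records:
            extra_map = dict(t.extras)
            writer.writerow(
                [
                    t.chemical.term,
                    t.chemical.accession,
                    t.gene.term,
                    t.gene.accession,
                    t.phenotype.term,
                    t.phenotype.accession,
                    t.disease.term,
                    t.disease.accession,
                ]
                + [extra_map.get(c, "") for c in extra_cols]
            )
            n += 1
        return n
    finally:
        if own:
            handle.close()


def write_dimer_csv(table, sink: Union[str, Path, IO[str]],
                    dialect: CsvDialect = CsvDialect()) -> int:
    """Export a dimer table as a 4-column edge list for graph tools.

    Columns: class, source, target, frequency.  Returns rows written.
    """
    own = isinstance(sink, (str, Path))
    handle: IO[str] = (
        open(sink, "w", newline="", encoding=dialect.encoding) if own else sink
    )
    try:
        writer = csv.writer(handle, delimiter=dialect.delimiter,
                            lineterminator="\n")
        writer.writerow(["class", "source", "target", "frequency"])
        n = 0
        for d in table.dimers:
            writer.writerow([d.dimer_class.value, d.source.term,
                             d.target.term, d.frequency])
            n += 1
        return n
    finally:
        if own:
            handle.close()


_KIND_ALIASES = {k.value: k for k in InteractionKind}
_KIND_ALIASES.update({k.value.replace("_", "-"): k for k in InteractionKind})

_INTERACTION_COLUMNS = (
    "kind",
    "subject_term",
    "subject_id",
    "object_term",
    "object_id",
)


def read_interaction_table(
    source: Source, dialect: CsvDialect = CsvDialect()
) -> list[InteractionRecord]:
    """Parse a curated interaction table (CSV or TSV via ``dialect``)."""
    df = _as_dataframe(source, dialect)
    norm = {c.strip().casefold(): c for c in df.columns}
    missing = [c for c in _INTERACTION_COLUMNS if c not in norm]
    if missing:
        raise MissingColumnsError(missing)
    out: list[InteractionRecord] = []
    for row in df.itertuples(index=False, name=None):
        cells = {c: str(row[df.columns.get_loc(norm[c])]).strip()
                 for c in _INTERACTION_COLUMNS}
        kind_key = cells["kind"].strip().casefold()
        kind = _KIND_ALIASES.get(kind_key)
        if kind is None:
            raise ValueError(
                f"unknown interaction kind {cells['kind']!r}; expected one of "
                + ", ".join(sorted(k.value for k in InteractionKind))
            )
        out.append(
            InteractionRecord(
                kind=kind,
                subject=TermRef(
                    term=cells["subject_term"],
                    accession=cells["subject_id"],
                    node_class=kind.subject_class,
                ),
                object=TermRef(
                    term=cells["object_term"],
                    accession=cells["object_id"],
                    node_class=kind.object_class,
                ),
            )
        )
    return out


def read_hierarchy_edges(
    source: Source,
    node_class: NodeClass,
    dialect: CsvDialect = CsvDialect(),
) -> TermHierarchy:
    """Parse a two-column ``parent_id, child_id`` edge list.

    A header row is optional; one is recognized by its column names.
    """
    df = pd.read_csv(
        source,
        sep=dialect.delimiter,
        dtype=str,
        keep_default_na=False,
        header=None,
        encoding=dialect.encoding,
    )
    if df.shape[1] < 2:
        raise ValueError("hierarchy edge list needs two columns")
    first = [str(v).strip().casefold() for v in df.iloc[0, :2]]
    if first == ["parent_id", "child_id"]:
        df = df.iloc[1:]
    edges = {
        (str(p).strip(), str(c).strip())
        for p, c in zip(df.iloc[:, 0], df.iloc[:, 1])
        if str(p).strip() and str(c).strip()
    }
    return TermHierarchy.from_edges(node_class, edges)


def load_database(
    interaction_sources: Iterable[Source],
    hierarchy_sources: dict[NodeClass, Source] | None = None,
    dialect: CsvDialect = CsvDialect(),
) -> CuratedDatabase:
    """Assemble a :class:`CuratedDatabase` from table files."""
    interactions: list[InteractionRecord] = []
    for src in interaction_sources:
        interactions.extend(read_interaction_table(src, dialect))
    hierarchy = {
        cls: read_hierarchy_edges(src, cls, dialect)
        for cls, src in (hierarchy_sources or {}).items()
    }
    return CuratedDatabase(interactions=interactions, hierarchy=hierarchy)
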