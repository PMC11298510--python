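"""Construct, filter, merge and summarize CGPD-tetramer sets.

The central operation is :func:`generate_tetramers`, the five-way join:
a quadruple (c, g, p, d) is emitted iff all five curated relations
chemical-gene(c,g), chemical-phenotype(c,p), chemical-disease(c,d),
gene-phenotype(g,p) and gene-disease(g,d) exist in the database.  The
join iterates chemical-gene pairs and intersects the phenotype and
disease neighbourhoods of c and g, which is equivalent to (and much
cheaper than) enumerating the full cross product.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx

from .model import (
    CuratedDatabase,
    Diagnostics,
    InteractionKind,
    NodeClass,
    QueryFilter,
    TermHierarchy,
    TermRef,
    Tetramer,
    TetramerSet,
)

__all__ = [
    "generate_tetramers",
    "expand_descendants",
    "filter_tetramers",
    "merge_tetramer_sets",
    "summarize",
    "TetramerSummary",
]


def expand_descendants(
    hierarchy: TermHierarchy,
    roots: Iterable[str],
    diagnostics: Optional[Diagnostics] = None,
) -> set[str]:
    """Transitive closure of ``roots`` under parent -> child edges.

    Roots are always included in the result.  A root absent from the
    hierarchy is returned alone, with a note in ``diagnostics``.
    """
    g = nx.DiGraph()
    g.add_edges_from(hierarchy.edges)
    out: set[str] = set()
    for root in roots:
        out.add(root)
        if root in g:
            out |= nx.descendants(g, root)
        elif diagnostics is not None:
            diagnostics.warn(
                f"accession {root!r} not found in the "
                f"{hierarchy.node_class.value} hierarchy; no descendants expanded"
            )
    return out


def _resolve_filter(
    db: CuratedDatabase, query: QueryFilter, diagnostics: Diagnostics
) -> dict[NodeClass, Optional[frozenset[str]]]:
    """Descendant-expand per-class accession sets; None = unconstrained.

    Unknown accessions are warned about and left in the set, where they
    simply match nothing.
    """
    known: dict[NodeClass, set[str]] = {c: set() for c in NodeClass}
    for rec in db.interactions:
        known[rec.subject.node_class].add(rec.subject.accession)
        known[rec.object.node_class].add(rec.object.accession)

    resolved: dict[NodeClass, Optional[frozenset[str]]] = {}
    for node_class in NodeClass:
        if not query.constrained(node_class):
            resolved[node_class] = None
            continue
        accs = set(query.accessions[node_class])
        if query.wants_descendants(node_class):
            hier = db.hierarchy.get(node_class)
            if hier is not None:
                accs = expand_descendants(hier, accs, diagnostics)
            else:
                diagnostics.warn(
                    f"descendant expansion requested for {node_class.value} "
                    "but no hierarchy was provided; using the roots as-is"
                )
        unknown = accs - known[node_class] - (
            db.hierarchy[node_class].accessions
            if node_class in db.hierarchy
            else frozenset()
        )
        for acc in sorted(unknown):
            diagnostics.warn(
                f"filter accession {acc!r} ({node_class.value}) matches no "
                "record in the database"
            )
        resolved[node_class] = frozenset(accs)
    return resolved


def _sort_key(t: Tetramer) -> tuple:
    # alphabetical by display term, case-insensitive, ties by accession
    return tuple(
        x for ref in t.slots for x in (ref.term.casefold(), ref.accession)
    )


def generate_tetramers(
    db: CuratedDatabase, query: Optional[QueryFilter] = None
) -> TetramerSet:
    """Emit every quadruple supported by all five curated relations.

    The output is deduplicated, intersected with the (descendant
    expanded) query filter, and sorted alphabetically by display terms
    (chemical, gene, phenotype, disease), ties broken by accession.
    Filter problems are reported on the returned set's ``diagnostics``.
    """
    query = query or QueryFilter()
    diagnostics = Diagnostics()
    allowed = _resolve_filter(db, query, diagnostics)

    refs: dict[tuple[str, str], TermRef] = {}
    for rec in db.interactions:
        refs.setdefault(rec.subject.key, rec.subject)
        refs.setdefault(rec.object.key, rec.object)

    def neighbours(kind: InteractionKind) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {}
        for s, o in db.pair_set(kind):
            adj.setdefault(s, set()).add(o)
        return adj

    cg = db.pair_set(InteractionKind.CHEMICAL_GENE)
    cp = neighbours(InteractionKind.CHEMICAL_PHENOTYPE)
    cd = neighbours(InteractionKind.CHEMICAL_DISEASE)
    gp = neighbours(InteractionKind.GENE_PHENOTYPE)
    gd = neighbours(InteractionKind.GENE_DISEASE)

    def pass_filter(node_class: NodeClass, acc: str) -> bool:
        a = allowed[node_class]
        return a is None or acc in a

    records: list[Tetramer] = []
    for c_acc, g_acc in cg:
        if not pass_filter(NodeClass.CHEMICAL, c_acc):
            continue
        if not pass_filter(NodeClass.GENE, g_acc):
            continue
        phenos = cp.get(c_acc, set()) & gp.get(g_acc, set())
        if not phenos:
            continue
        diseases = cd.get(c_acc, set()) & gd.get(g_acc, set())
        if not diseases:
            continue
        for p_acc in phenos:
            if not pass_filter(NodeClass.PHENOTYPE, p_acc):
                continue
            for d_acc in diseases:
                if not pass_filter(NodeClass.DISEASE, d_acc):
                    continue
                records.append(
                    Tetramer(
                        chemical=refs[(c_acc, NodeClass.CHEMICAL.value)],
                        gene=refs[(g_acc, NodeClass.GENE.value)],
                        phenotype=refs[(p_acc, NodeClass.PHENOTYPE.value)],
                        disease=refs[(d_acc, NodeClass.DISEASE.value)],
                    )
                )

    records.sort(key=_sort_key)
    return TetramerSet(
        records=records, source_label="generated", diagnostics=diagnostics
    )


def filter_tetramers(
    tset: TetramerSet,
    query: QueryFilter,
    hierarchy: Optional[dict[NodeClass, TermHierarchy]] = None,
) -> TetramerSet:
    """Keep records whose slot accessions fall inside the filter sets.

    Unconstrained classes pass everything; record order is preserved.
    Descendant expansion uses ``hierarchy`` when the filter asks for it.
    """
    diagnostics = Diagnostics()
    allowed: dict[NodeClass, Optional[frozenset[str]]] = {}
    for node_class in NodeClass:
        if not query.constrained(node_class):
            allowed[node_class] = None
            continue
        accs = set(query.accessions[node_class])
        if query.wants_descendants(node_class):
            hier = (hierarchy or {}).get(node_class)
            if hier is not None:
                accs = expand_descendants(hier, accs, diagnostics)
            else:
                diagnostics.warn(
                    f"descendant expansion requested for {node_class.value} "
                    "but no hierarchy was provided; using the roots as-is"
                )
        allowed[node_class] = frozenset(accs)

    def keep(t: Tetramer) -> bool:
        for ref in t.slots:
            a = allowed[ref.node_class]
            if a is not None and ref.accession not in a:
                return False
        return True

    return TetramerSet(
        records=[t for t in tset.records if keep(t)],
        source_label=tset.source_label,
        diagnostics=diagnostics,
    )


def merge_tetramer_sets(
    sets: Sequence[TetramerSet], deduplicate: bool = False
) -> TetramerSet:
    """Concatenate tetramer sets, optionally deduplicating.

    The default (``deduplicate=False``) is plain concatenation in input
    order, matching the manual copy-and-paste merge of separate query
    downloads; with ``deduplicate=True`` only the first occurrence of
    each accession 4-tuple is kept.
    """
    if not sets:
        raise ValueError("merge_tetramer_sets requires at least one input set")
    records: list[Tetramer] = []
    for s in sets:
        records.extend(s.records)
    label = " + ".join(s.source_label or "<unlabelled>" for s in sets)
    merged = TetramerSet(records=records, source_label=label)
    return merged.unique() if deduplicate else merged


@dataclass
class TetramerSummary:
    """Record counts plus per-class unique term counts (on accessions)."""

    records: int
    unique_tetramers: int
    chemicals: int
    genes: int
    phenotypes: int
    diseases: int

    def to_dict(self) -> dict[str, int]:
        return {
            "records": self.records,
            "unique_tetramers": self.unique_tetramers,
            "chemicals": self.chemicals,
            "genes": self.genes,
            "phenotypes": self.phenotypes,
            "diseases": self.diseases,
        }


def summarize(tset: TetramerSet) -> TetramerSummary:
    """Count records, unique tetramers, and unique terms per class."""
    return TetramerSummary(
        records=len(tset),
        unique_tetramers=tset.unique_count(),
        chemicals=len({t.chemical.accession for t in tset}),
        genes=len({t.gene.accession for t in tset}),
        phenotypes=len({t.phenotype.accession for t in tset}),
        diseases=len({t.disease.accession for t in tset}),
    )
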