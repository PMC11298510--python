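"""Core domain types for CGPD-tetramer analysis.

A CGPD-tetramer is a four-unit block -- Chemical, Gene, Phenotype,
Disease -- asserted only when five independently curated pairwise
relations among its members all exist in the source database:
chemical-gene, chemical-phenotype, chemical-disease, gene-phenotype and
gene-disease.  These types model the curated input relations, the
tetramers themselves, and the query filters used to constrain them.

Identity conventions
--------------------
Nodes are keyed by ``(accession, node_class)``: accession strings are
opaque, compared exactly and case-sensitively, and a display term may be
shared across classes without ever merging nodes.  A tetramer's identity
is its 4-tuple of accessions; display terms are presentation only.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional

__all__ = [
    "NodeClass",
    "TermRef",
    "InteractionKind",
    "InteractionRecord",
    "TermHierarchy",
    "CuratedDatabase",
    "Tetramer",
    "TetramerSet",
    "QueryFilter",
    "Diagnostics",
    "MalformedDatabaseError",
]


class NodeClass(enum.Enum):
    """The four node classes, in clockwise reading order C < G < P < D."""

    CHEMICAL = "chemical"
    GENE = "gene"
    PHENOTYPE = "phenotype"
    DISEASE = "disease"

    @property
    def order(self) -> int:
        return _CLASS_ORDER[self]

    def __lt__(self, other: "NodeClass") -> bool:
        if not isinstance(other, NodeClass):
            return NotImplemented
        return self.order < other.order


_CLASS_ORDER = {
    NodeClass.CHEMICAL: 0,
    NodeClass.GENE: 1,
    NodeClass.PHENOTYPE: 2,
    NodeClass.DISEASE: 3,
}


@dataclass(frozen=True)
class TermRef:
    """A node: display term plus accession identifier plus class.

    ``accession`` comparison is exact and case-sensitive; ``term`` is
    free text and purely presentational.
    """

    term: str
    accession: str
    node_class: NodeClass

    def __post_init__(self) -> None:
        if not self.term:
            raise ValueError("TermRef.term must be non-empty")
        if not self.accession:
            raise ValueError("TermRef.accession must be non-empty")

    @property
    def key(self) -> tuple[str, str]:
        return (self.accession, self.node_class.value)


class InteractionKind(enum.Enum):
    """The five curated relation kinds supporting a tetramer."""

    CHEMICAL_GENE = "chemical_gene"
    CHEMICAL_PHENOTYPE = "chemical_phenotype"
    CHEMICAL_DISEASE = "chemical_disease"
    GENE_DISEASE = "gene_disease"
    GENE_PHENOTYPE = "gene_phenotype"

    @property
    def subject_class(self) -> NodeClass:
        return _KIND_CLASSES[self][0]

    @property
    def object_class(self) -> NodeClass:
        return _KIND_CLASSES[self][1]


_KIND_CLASSES = {
    InteractionKind.CHEMICAL_GENE: (NodeClass.CHEMICAL, NodeClass.GENE),
    InteractionKind.CHEMICAL_PHENOTYPE: (NodeClass.CHEMICAL, NodeClass.PHENOTYPE),
    InteractionKind.CHEMICAL_DISEASE: (NodeClass.CHEMICAL, NodeClass.DISEASE),
    InteractionKind.GENE_DISEASE: (NodeClass.GENE, NodeClass.DISEASE),
    InteractionKind.GENE_PHENOTYPE: (NodeClass.GENE, NodeClass.PHENOTYPE),
}


class MalformedDatabaseError(ValueError):
    """A curated record violates the schema; the message names it."""


@dataclass(frozen=True)
class InteractionRecord:
    """One curated subject-object relation of one of the five kinds."""

    kind: InteractionKind
    subject: TermRef
    object: TermRef

    def __post_init__(self) -> None:
        if self.subject.node_class is not self.kind.subject_class:
            raise MalformedDatabaseError(
                f"{self.kind.value} record subject {self.subject.accession!r} has "
                f"class {self.subject.node_class.value}, expected "
                f"{self.kind.subject_class.value}"
            )
        if self.object.node_class is not self.kind.object_class:
            raise MalformedDatabaseError(
                f"{self.kind.value} record object {self.object.accession!r} has "
                f"class {self.object.node_class.value}, expected "
                f"{self.kind.object_class.value}"
            )


@dataclass
class Diagnostics:
    """Accumulated non-fatal warnings from an operation."""

    warnings: list[str] = field(default_factory=list)
    skipped_rows: int = 0

    def warn(self, message: str) -> None:
        self.warnings.append(message)

    def __bool__(self) -> bool:
        return bool(self.warnings) or self.skipped_rows > 0


@dataclass(frozen=True)
class TermHierarchy:
    """Acyclic parent -> child accession graph for one node class."""

    node_class: NodeClass
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        # cycle check via networkx; hierarchies are small curated DAGs
        import networkx as nx

        g = nx.DiGraph()
        g.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError(
                f"{self.node_class.value} hierarchy contains a cycle"
            )

    @classmethod
    def from_edges(
        cls, node_class: NodeClass, edges: Iterable[tuple[str, str]]
    ) -> "TermHierarchy":
        return cls(node_class=node_class, edges=frozenset(edges))

    @property
    def accessions(self) -> frozenset[str]:
        return frozenset(a for e in self.edges for a in e)


@dataclass
class CuratedDatabase:
    """A set of curated interactions plus optional per-class hierarchies.

    Duplicate ``(kind, subject accession, object accession)`` triples are
    collapsed on construction (first occurrence kept).
    """

    interactions: list[InteractionRecord]
    hierarchy: dict[NodeClass, TermHierarchy] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, str]] = set()
        unique: list[InteractionRecord] = []
        for rec in self.interactions:
            key = (rec.kind.value, rec.subject.accession, rec.object.accession)
            if key not in seen:
                seen.add(key)
                unique.append(rec)
        self.interactions = unique

    def by_kind(self, kind: InteractionKind) -> list[InteractionRecord]:
        return [r for r in self.interactions if r.kind is kind]

    def pair_set(self, kind: InteractionKind) -> set[tuple[str, str]]:
        """Accession pairs (subject, object) present for a kind."""
        return {
            (r.subject.accession, r.object.accession) for r in self.by_kind(kind)
        }


@dataclass(frozen=True)
class Tetramer:
    """An ordered (chemical, gene, phenotype, disease) quadruple.

    ``extras`` carries opaque annotation columns from CSV sources, as a
    sorted tuple of (column, value) pairs so the record stays hashable.
    """

    chemical: TermRef
    gene: TermRef
    phenotype: TermRef
    disease: TermRef
    extras: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        for slot, cls in (
            ("chemical", NodeClass.CHEMICAL),
            ("gene", NodeClass.GENE),
            ("phenotype", NodeClass.PHENOTYPE),
            ("disease", NodeClass.DISEASE),
        ):
            ref: TermRef = getattr(self, slot)
            if ref.node_class is not cls:
                raise ValueError(
                    f"tetramer slot {slot} holds a {ref.node_class.value} node"
                )

    @property
    def key(self) -> tuple[str, str, str, str]:
        """Identity: the 4-tuple of accessions."""
        return (
            self.chemical.accession,
            self.gene.accession,
            self.phenotype.accession,
            self.disease.accession,
        )

    @property
    def slots(self) -> tuple[TermRef, TermRef, TermRef, TermRef]:
        return (self.chemical, self.gene, self.phenotype, self.disease)


@dataclass
class TetramerSet:
    """An ordered collection of tetramers with a provenance label.

    Order is stable under CSV round-trips; duplicates are allowed (a CSV
    download is row-faithful) and uniqueness is computed on demand.
    """

    records: list[Tetramer] = field(default_factory=list)
    source_label: str = ""
    diagnostics: Diagnostics = field(default_factory=Diagnostics)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Tetramer]:
        return iter(self.records)

    def unique(self) -> "TetramerSet":
        """First-occurrence deduplication on accession 4-tuples."""
        seen: set[tuple[str, str, str, str]] = set()
        out: list[Tetramer] = []
        for t in self.records:
            if t.key not in seen:
                seen.add(t.key)
                out.append(t)
        return TetramerSet(records=out, source_label=self.source_label)

    def unique_count(self) -> int:
        return len({t.key for t in self.records})


@dataclass(frozen=True)
class QueryFilter:
    """Per-class accession constraints; an absent set means unconstrained."""

    accessions: Mapping[NodeClass, frozenset[str]] = field(default_factory=dict)
    include_descendants: Mapping[NodeClass, bool] = field(default_factory=dict)

    @classmethod
    def build(
        cls,
        chemicals: Optional[Iterable[str]] = None,
        genes: Optional[Iterable[str]] = None,
        phenotypes: Optional[Iterable[str]] = None,
        diseases: Optional[Iterable[str]] = None,
        descendants: Optional[Iterable[NodeClass]] = None,
    ) -> "QueryFilter":
        acc: dict[NodeClass, frozenset[str]] = {}
        for cls_, vals in (
            (NodeClass.CHEMICAL, chemicals),
            (NodeClass.GENE, genes),
            (NodeClass.PHENOTYPE, phenotypes),
            (NodeClass.DISEASE, diseases),
        ):
            if vals is not None:
                acc[cls_] = frozenset(vals)
        desc = {c: True for c in (descendants or [])}
        return cls(accessions=acc, include_descendants=desc)

    def constrained(self, node_class: NodeClass) -> bool:
        return node_class in self.accessions and bool(self.accessions[node_class])

    def wants_descendants(self, node_class: NodeClass) -> bool:
        return bool(self.include_descendants.get(node_class, False))

    def is_empty(self) -> bool:
        return not any(self.accessions.get(c) for c in NodeClass)
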