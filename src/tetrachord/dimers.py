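"""Decompose tetramer sets into directed dimers with support frequencies.

Each unique tetramer contributes exactly one occurrence to each of the
three adjacent dimer classes read clockwise: chemical->gene (CG),
gene->phenotype (GP) and phenotype->disease (PD).  Aggregating
occurrences by (class, source, target) yields the dimer table; summing
a node's incident dimer frequencies yields its weight, the quantity
that scales its sector in the chord diagram.

Because every tetramer contributes once per class, the per-class
frequency totals each equal the number of unique tetramers, and end
class nodes (chemicals, diseases) weigh their participation count while
middle-class nodes (genes, phenotypes) weigh twice it -- the only
weighting under which ribbons exactly tile their sectors.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable

from .model import NodeClass, TermRef, Tetramer, TetramerSet

__all__ = ["DimerClass", "Dimer", "DimerTable", "NodeWeight",
           "decompose", "node_weights", "dimer_table_to_rows"]


class DimerClass(enum.Enum):
    """The three adjacent pair classes, in clockwise reading order."""

    CHEMICAL_GENE = "chemical_gene"
    GENE_PHENOTYPE = "gene_phenotype"
    PHENOTYPE_DISEASE = "phenotype_disease"

    @property
    def source_class(self) -> NodeClass:
        return _DIMER_CLASSES[self][0]

    @property
    def target_class(self) -> NodeClass:
        return _DIMER_CLASSES[self][1]

    @property
    def order(self) -> int:
        return _DIMER_ORDER[self]


_DIMER_CLASSES = {
    DimerClass.CHEMICAL_GENE: (NodeClass.CHEMICAL, NodeClass.GENE),
    DimerClass.GENE_PHENOTYPE: (NodeClass.GENE, NodeClass.PHENOTYPE),
    DimerClass.PHENOTYPE_DISEASE: (NodeClass.PHENOTYPE, NodeClass.DISEASE),
}
_DIMER_ORDER = {
    DimerClass.CHEMICAL_GENE: 0,
    DimerClass.GENE_PHENOTYPE: 1,
    DimerClass.PHENOTYPE_DISEASE: 2,
}


@dataclass(frozen=True)
class Dimer:
    """A directed class edge with its tetramer-support frequency."""

    dimer_class: DimerClass
    source: TermRef
    target: TermRef
    frequency: int

    def __post_init__(self) -> None:
        if self.frequency < 1:
            raise ValueError("dimer frequency must be >= 1")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.dimer_class.value, self.source.accession,
                self.target.accession)


@dataclass
class DimerTable:
    """Aggregated dimers from one deduplicated tetramer set."""

    dimers: list[Dimer] = field(default_factory=list)
    n_tetramers: int = 0

    def by_class(self, dimer_class: DimerClass) -> list[Dimer]:
        return [d for d in self.dimers if d.dimer_class is dimer_class]

    def class_total(self, dimer_class: DimerClass) -> int:
        return sum(d.frequency for d in self.by_class(dimer_class))


@dataclass(frozen=True)
class NodeWeight:
    """A node and the sum of its incident dimer frequencies."""

    node: TermRef
    weight: int


def _slot_pairs(t: Tetramer) -> Iterable[tuple[DimerClass, TermRef, TermRef]]:
    yield DimerClass.CHEMICAL_GENE, t.chemical, t.gene
    yield DimerClass.GENE_PHENOTYPE, t.gene, t.phenotype
    yield DimerClass.PHENOTYPE_DISEASE, t.phenotype, t.disease


def decompose(tset: TetramerSet, use_ids: bool = False) -> DimerTable:
    """Tally CG/GP/PD dimer occurrences over the unique tetramers.

    ``use_ids=True`` replaces each node's display term with its
    accession -- a relabelling only; frequencies are unaffected.  The
    input is deduplicated internally so frequencies count unique
    tetramers, never CSV rows.
    """
    unique = tset.unique()
    counts: dict[tuple[str, str, str], int] = {}
    refs: dict[tuple[str, str, str], tuple[TermRef, TermRef]] = {}
    order: list[tuple[str, str, str]] = []
    for t in unique:
        for dclass, src, tgt in _slot_pairs(t):
            key = (dclass.value, src.accession, tgt.accession)
            if key not in counts:
                counts[key] = 0
                refs[key] = (src, tgt)
                order.append(key)
            counts[key] += 1

    def relabel(ref: TermRef) -> TermRef:
        if not use_ids:
            return ref
        return TermRef(term=ref.accession, accession=ref.accession,
                       node_class=ref.node_class)

    dimers = [
        Dimer(
            dimer_class=DimerClass(key[0]),
            source=relabel(refs[key][0]),
            target=relabel(refs[key][1]),
            frequency=counts[key],
        )
        for key in order
    ]
    dimers.sort(key=lambda d: (d.dimer_class.order,
                               d.source.accession, d.target.accession))
    return DimerTable(dimers=dimers, n_tetramers=len(unique.records))


def node_weights(table: DimerTable) -> list[NodeWeight]:
    """Weight of every node appearing in the table.

    A node's weight is the sum of frequencies over all dimers incident
    to it, so chemicals count outgoing CG, diseases incoming PD, and
    genes/phenotypes both directions.
    """
    weights: dict[tuple[str, str], int] = {}
    refs: dict[tuple[str, str], TermRef] = {}
    for d in table.dimers:
        for ref in (d.source, d.target):
            weights[ref.key] = weights.get(ref.key, 0) + d.frequency
            refs.setdefault(ref.key, ref)
    out = [NodeWeight(node=refs[k], weight=w) for k, w in weights.items()]
    out.sort(key=lambda nw: (nw.node.node_class.order, nw.node.accession))
    return out


def dimer_table_to_rows(table: DimerTable) -> list[tuple[str, str, str, int]]:
    """Edge-list export rows: (class, source term, target term, frequency)."""
    return [(d.dimer_class.value, d.source.term, d.target.term, d.frequency)
            for d in table.dimers]
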