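"""Seeded synthetic fixtures: curated databases, tetramer tables, hierarchies.

Everything here is generated, deterministic under its seed, and uses a
synthetic accession scheme (``C0001``/``G0001``/``P0001``/``D0001``) so
node classes stay unambiguous without real MeSH or NCBI Gene
identifiers.  Databases come paired with their brute-force-enumerated
tetramer closure so the five-way join can always be checked against an
oracle computed by exhaustive quadruple enumeration.

:func:`ozone_toy` and :func:`testcsv_like` are worked-example fixtures:
the former is a consistent reconstruction of a three-tetramer
ozone/airway-obstruction schematic, the latter mimics only the *shape*
of a published 309-tetramer metals/liver-neoplasms query download
(2 chemicals, 61 genes, 87 phenotypes, 1 disease) with synthetic gene
and phenotype content.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .model import (
    CuratedDatabase,
    InteractionKind,
    InteractionRecord,
    NodeClass,
    TermHierarchy,
    TermRef,
    Tetramer,
    TetramerSet,
)

__all__ = [
    "FixtureSpec",
    "make_database",
    "make_tetramer_table",
    "make_disjoint_tables",
    "make_overlapping_pair",
    "make_hierarchy",
    "ozone_toy",
    "testcsv_like",
]

_PREFIX = {
    NodeClass.CHEMICAL: "C",
    NodeClass.GENE: "G",
    NodeClass.PHENOTYPE: "P",
    NodeClass.DISEASE: "D",
}
_TERM_STEM = {
    NodeClass.CHEMICAL: "chem",
    NodeClass.GENE: "gene",
    NodeClass.PHENOTYPE: "phen",
    NodeClass.DISEASE: "dis",
}


def _node(node_class: NodeClass, i: int) -> TermRef:
    return TermRef(
        term=f"{_TERM_STEM[node_class]}-{i:04d}",
        accession=f"{_PREFIX[node_class]}{i:04d}",
        node_class=node_class,
    )


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters for a synthetic curated database.

    ``interaction_probability`` is the independent inclusion probability
    applied to every candidate pair of each of the five kinds;
    ``planted`` quadruples additionally get all five supporting
    interactions, guaranteeing at least that many complete tetramers.
    """

    n_chemicals: int = 10
    n_genes: int = 20
    n_phenotypes: int = 20
    n_diseases: int = 5
    interaction_probability: float = 0.3
    planted: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.interaction_probability <= 1.0:
            raise ValueError("interaction_probability must lie in [0, 1]")
        for name in ("n_chemicals", "n_genes", "n_phenotypes", "n_diseases"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.planted < 0:
            raise ValueError("planted must be >= 0")


def brute_force_tetramers(db: CuratedDatabase) -> TetramerSet:
    """Exhaustive oracle: test all five memberships over every quadruple.

    Intended for small databases (up to ~1e5 candidate quadruples); the
    production join in :mod:`tetrachord.engine` must agree with this.
    """
    refs: dict[NodeClass, dict[str, TermRef]] = {c: {} for c in NodeClass}
    for rec in db.interactions:
        for ref in (rec.subject, rec.object):
            refs[ref.node_class].setdefault(ref.accession, ref)
    cg = db.pair_set(InteractionKind.CHEMICAL_GENE)
    cp = db.pair_set(InteractionKind.CHEMICAL_PHENOTYPE)
    cd = db.pair_set(InteractionKind.CHEMICAL_DISEASE)
    gp = db.pair_set(InteractionKind.GENE_PHENOTYPE)
    gd = db.pair_set(InteractionKind.GENE_DISEASE)
    records = []
    for c, g, p, d in itertools.product(
        sorted(refs[NodeClass.CHEMICAL]),
        sorted(refs[NodeClass.GENE]),
        sorted(refs[NodeClass.PHENOTYPE]),
        sorted(refs[NodeClass.DISEASE]),
    ):
        if ((c, g) in cg and (c, p) in cp and (c, d) in cd
                and (g, p) in gp and (g, d) in gd):
            records.append(Tetramer(
                chemical=refs[NodeClass.CHEMICAL][c],
                gene=refs[NodeClass.GENE][g],
                phenotype=refs[NodeClass.PHENOTYPE][p],
                disease=refs[NodeClass.DISEASE][d],
            ))
    records.sort(key=lambda t: tuple(
        x for ref in t.slots for x in (ref.term.casefold(), ref.accession)))
    return TetramerSet(records=records, source_label="brute-force oracle")


def make_database(spec: FixtureSpec) -> tuple[CuratedDatabase, TetramerSet]:
    """Random curated database plus its brute-force tetramer closure."""
    rng = np.random.default_rng(spec.seed)
    nodes = {
        NodeClass.CHEMICAL: [_node(NodeClass.CHEMICAL, i)
                             for i in range(spec.n_chemicals)],
        NodeClass.GENE: [_node(NodeClass.GENE, i)
                         for i in range(spec.n_genes)],
        NodeClass.PHENOTYPE: [_node(NodeClass.PHENOTYPE, i)
                              for i in range(spec.n_phenotypes)],
        NodeClass.DISEASE: [_node(NodeClass.DISEASE, i)
                            for i in range(spec.n_diseases)],
    }
    interactions: list[InteractionRecord] = []
    for kind in InteractionKind:
        subjects = nodes[kind.subject_class]
        objects = nodes[kind.object_class]
        if spec.interaction_probability > 0:
            # one integer draw per candidate pair keeps this platform-stable
            draws = rng.integers(0, 1_000_000,
                                 size=(len(subjects), len(objects)))
            thresh = spec.interaction_probability * 1_000_000
            for i, s in enumerate(subjects):
                for j, o in enumerate(objects):
                    if draws[i, j] < thresh:
                        interactions.append(
                            InteractionRecord(kind=kind, subject=s, object=o))

    # each planted quadruple gets its own chemical (when enough exist):
    # with zero background probability no cross-quadruple combination can
    # then complete all five relations, so exactly `planted` tetramers
    # are guaranteed
    for k in range(spec.planted):
        c = nodes[NodeClass.CHEMICAL][k % spec.n_chemicals]
        g = nodes[NodeClass.GENE][int(rng.integers(spec.n_genes))]
        p = nodes[NodeClass.PHENOTYPE][int(rng.integers(spec.n_phenotypes))]
        d = nodes[NodeClass.DISEASE][int(rng.integers(spec.n_diseases))]
        interactions.extend([
            InteractionRecord(InteractionKind.CHEMICAL_GENE, c, g),
            InteractionRecord(InteractionKind.CHEMICAL_PHENOTYPE, c, p),
            InteractionRecord(InteractionKind.CHEMICAL_DISEASE, c, d),
            InteractionRecord(InteractionKind.GENE_PHENOTYPE, g, p),
            InteractionRecord(InteractionKind.GENE_DISEASE, g, d),
        ])

    db = CuratedDatabase(interactions=interactions)
    return db, brute_force_tetramers(db)


def _sample_unique_quadruples(
    n: int,
    cardinalities: tuple[int, int, int, int],
    rng: np.random.Generator,
) -> list[tuple[int, int, int, int]]:
    nc, ng, np_, nd = cardinalities
    total = nc * ng * np_ * nd
    if n > total:
        raise ValueError(
            f"cannot draw {n} unique tetramers from only {total} possible "
            f"combinations"
        )
    flat = rng.choice(total, size=n, replace=False)
    out = []
    for f in sorted(int(v) for v in flat):
        d = f % nd
        f //= nd
        p = f % np_
        f //= np_
        g = f % ng
        c = f // ng
        out.append((c, g, p, d))
    # shuffle so record order is not index-sorted
    perm = rng.permutation(n)
    return [out[int(i)] for i in perm]


def make_tetramer_table(
    n: int,
    cardinalities: tuple[int, int, int, int] = (5, 40, 60, 3),
    seed: int = 0,
    source_label: str = "synthetic",
) -> TetramerSet:
    """``n`` unique random tetramers over the given class cardinalities."""
    rng = np.random.default_rng(seed)
    quads = _sample_unique_quadruples(n, cardinalities, rng)
    records = [
        Tetramer(
            chemical=_node(NodeClass.CHEMICAL, c),
            gene=_node(NodeClass.GENE, g),
            phenotype=_node(NodeClass.PHENOTYPE, p),
            disease=_node(NodeClass.DISEASE, d),
        )
        for c, g, p, d in quads
    ]
    return TetramerSet(records=records, source_label=source_label)


def make_disjoint_tables(
    sizes: list[int],
    cardinalities: tuple[int, int, int, int] = (5, 40, 60, 3),
    seed: int = 0,
) -> list[TetramerSet]:
    """Tetramer tables guaranteed pairwise disjoint (split of one draw)."""
    total = sum(sizes)
    pool = make_tetramer_table(total, cardinalities, seed)
    out = []
    start = 0
    for i, size in enumerate(sizes):
        out.append(TetramerSet(
            records=pool.records[start:start + size],
            source_label=f"query-{i + 1}",
        ))
        start += size
    return out


def make_overlapping_pair(
    size_a: int,
    size_b: int,
    overlap: int,
    cardinalities: tuple[int, int, int, int] = (5, 40, 60, 3),
    seed: int = 0,
) -> tuple[TetramerSet, TetramerSet]:
    """Two tables sharing exactly ``overlap`` records."""
    if overlap > min(size_a, size_b):
        raise ValueError("overlap cannot exceed either table size")
    pool = make_tetramer_table(size_a + size_b - overlap, cardinalities, seed)
    a = TetramerSet(records=pool.records[:size_a], source_label="query-a")
    b = TetramerSet(records=pool.records[size_a - overlap:],
                    source_label="query-b")
    return a, b


def make_hierarchy(
    node_class: NodeClass,
    depth: int = 4,
    branching: int = 3,
    extra_edges: int = 0,
    seed: int = 0,
) -> TermHierarchy:
    """A rooted tree of the given depth/branching, plus optional extra
    forward edges (parent at a strictly shallower level), so the graph
    stays acyclic while exercising true DAG reachability."""
    rng = np.random.default_rng(seed)
    levels: list[list[str]] = [[f"{_PREFIX[node_class]}0000"]]
    edges: set[tuple[str, str]] = set()
    counter = 1
    for _ in range(depth):
        nxt: list[str] = []
        for parent in levels[-1]:
            for _ in range(branching):
                child = f"{_PREFIX[node_class]}{counter:04d}"
                counter += 1
                edges.add((parent, child))
                nxt.append(child)
        levels.append(nxt)
    for _ in range(extra_edges):
        li = int(rng.integers(0, len(levels) - 1))
        lj = int(rng.integers(li + 1, len(levels)))
        parent = levels[li][int(rng.integers(len(levels[li])))]
        child = levels[lj][int(rng.integers(len(levels[lj])))]
        if parent != child:
            edges.add((parent, child))
    return TermHierarchy.from_edges(node_class, edges)


def ozone_toy() -> TetramerSet:
    """Three-tetramer worked example: ozone to airway obstruction.

    A reconstruction (the exact printed rows of the original schematic
    are not public) consistent with its stated composition: one
    chemical (ozone), two genes (PTGFR, TFPI), two phenotypes
    (inflammatory response, response to lipopolysaccharide), one
    disease (airway obstruction), with PTGFR and response to
    lipopolysaccharide each supported by two of the three tetramers.
    """
    ozone = TermRef("Ozone", "D010126", NodeClass.CHEMICAL)
    ptgfr = TermRef("PTGFR", "5737", NodeClass.GENE)
    tfpi = TermRef("TFPI", "7035", NodeClass.GENE)
    infl = TermRef("inflammatory response", "GO:0006954", NodeClass.PHENOTYPE)
    lps = TermRef("response to lipopolysaccharide", "GO:0032496",
                  NodeClass.PHENOTYPE)
    airway = TermRef("Airway Obstruction", "D000402", NodeClass.DISEASE)
    records = [
        Tetramer(chemical=ozone, gene=ptgfr, phenotype=infl, disease=airway),
        Tetramer(chemical=ozone, gene=ptgfr, phenotype=lps, disease=airway),
        Tetramer(chemical=ozone, gene=tfpi, phenotype=lps, disease=airway),
    ]
    return TetramerSet(records=records, source_label="ozone-toy")


def testcsv_like(seed: int = 0) -> TetramerSet:
    """Synthetic stand-in shaped like a 309-tetramer metals query download.

    309 unique records over 2 chemicals (copper, iron), 61 synthetic
    genes, 87 synthetic phenotypes and 1 disease (liver neoplasms);
    every term of every class occurs in at least one record.  The gene
    and phenotype *content* is synthetic -- only the shape matches the
    published query result.
    """
    rng = np.random.default_rng(seed)
    chems = [TermRef("Copper", "D003300", NodeClass.CHEMICAL),
             TermRef("Iron", "D007501", NodeClass.CHEMICAL)]
    genes = [_node(NodeClass.GENE, i) for i in range(61)]
    phens = [_node(NodeClass.PHENOTYPE, i) for i in range(87)]
    disease = TermRef("Liver Neoplasms", "D008113", NodeClass.DISEASE)

    used: set[tuple[int, int, int]] = set()
    triples: list[tuple[int, int, int]] = []
    # coverage pass: every phenotype once, cycling genes and chemicals
    for i in range(87):
        t = (i % 2, i % 61, i)
        used.add(t)
        triples.append(t)
    while len(triples) < 309:
        t = (int(rng.integers(2)), int(rng.integers(61)),
             int(rng.integers(87)))
        if t not in used:
            used.add(t)
            triples.append(t)
    records = [
        Tetramer(chemical=chems[c], gene=genes[g], phenotype=phens[p],
                 disease=disease)
        for c, g, p in triples
    ]
    return TetramerSet(records=records, source_label="testcsv-like (synthetic)")
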