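import pytest

from tetrachord import (
    CuratedDatabase,
    InteractionKind,
    InteractionRecord,
    NodeClass,
    TermRef,
)


def _ref(term, acc, cls):
    return TermRef(term=term, accession=acc, node_class=cls)


@pytest.fixture
def minimal_quadruple():
    """One chemical/gene/phenotype/disease with names and accessions."""
    return dict(
        c=_ref("arsenic", "C1", NodeClass.CHEMICAL),
        g=_ref("BAX", "G1", NodeClass.GENE),
        p=_ref("apoptosis", "P1", NodeClass.PHENOTYPE),
        d=_ref("male infertility", "D1", NodeClass.DISEASE),
    )


def five_interactions(c, g, p, d):
    """The complete support set for one quadruple."""
    return [
        InteractionRecord(InteractionKind.CHEMICAL_GENE, c, g),
        InteractionRecord(InteractionKind.CHEMICAL_PHENOTYPE, c, p),
        InteractionRecord(InteractionKind.CHEMICAL_DISEASE, c, d),
        InteractionRecord(InteractionKind.GENE_PHENOTYPE, g, p),
        InteractionRecord(InteractionKind.GENE_DISEASE, g, d),
    ]


@pytest.fixture
def minimal_db(minimal_quadruple):
    q = minimal_quadruple
    return CuratedDatabase(
        interactions=five_interactions(q["c"], q["g"], q["p"], q["d"])
    )
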