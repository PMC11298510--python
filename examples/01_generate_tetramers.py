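"""Build a tiny curated database and join it into CGPD-tetramers.

A tetramer (chemical, gene, phenotype, disease) exists only when all
five pairwise curated relations among its members exist.  Here copper
supports a complete quadruple through HMOX1, while iron is missing its
chemical-disease link, so only one tetramer comes out.  A hierarchy filter
on the chemical class then shows a "metals" root query reaching its
descendant copper.
"""

from tetrachord import (
    CuratedDatabase,
    InteractionKind,
    InteractionRecord,
    NodeClass,
    QueryFilter,
    TermHierarchy,
    TermRef,
    generate_tetramers,
    summarize,
)

copper = TermRef("copper", "D003300", NodeClass.CHEMICAL)
iron = TermRef("iron", "D007501", NodeClass.CHEMICAL)
hmox1 = TermRef("HMOX1", "3162", NodeClass.GENE)
prolif = TermRef("cell proliferation", "GO:0008283", NodeClass.PHENOTYPE)
neoplasm = TermRef("Liver Neoplasms", "D008113", NodeClass.DISEASE)

K = InteractionKind
interactions = [
    # copper: all five relations -> one complete tetramer
    InteractionRecord(K.CHEMICAL_GENE, copper, hmox1),
    InteractionRecord(K.CHEMICAL_PHENOTYPE, copper, prolif),
    InteractionRecord(K.CHEMICAL_DISEASE, copper, neoplasm),
    InteractionRecord(K.GENE_PHENOTYPE, hmox1, prolif),
    InteractionRecord(K.GENE_DISEASE, hmox1, neoplasm),
    # iron: no chemical-disease relation -> no tetramer, even though
    # the gene-side relations above are shared
    InteractionRecord(K.CHEMICAL_GENE, iron, hmox1),
    InteractionRecord(K.CHEMICAL_PHENOTYPE, iron, prolif),
]
metals = TermHierarchy.from_edges(
    NodeClass.CHEMICAL, [("D008670", "D003300"), ("D008670", "D007501")])
db = CuratedDatabase(interactions=interactions,
                     hierarchy={NodeClass.CHEMICAL: metals})

tset = generate_tetramers(db)
print("unfiltered join:", summarize(tset).to_dict())
for t in tset:
    print("  ", " -> ".join(ref.term for ref in t.slots))

# querying the 'metals' root with descendant expansion reaches copper
query = QueryFilter.build(chemicals=["D008670"],
                          descendants=[NodeClass.CHEMICAL])
filtered = generate_tetramers(db, query)
print("metals-with-descendants query:", len(filtered), "tetramer(s)")
# The single surviving quadruple is the one with complete 5-relation
# support; dropping any one of its interactions would remove it.
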