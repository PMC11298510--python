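# tetrachord

Construct **CGPD-tetramers** — Chemical → Gene → Phenotype → Disease
blocks of toxicogenomic evidence — from curated interaction tables, and
transform them into **chord diagrams** with a deterministic geometry
engine and SVG renderer.

## The problem and who this is for

In environmental health, the molecular mechanism connecting a chemical
exposure to a disease outcome is often a knowledge gap. Databases of
manually curated literature interactions let that gap be bridged
computationally: a quadruple (c, g, p, d) is asserted as a candidate
step-wise mechanism — chemical *c* perturbs gene *g*, modulating
phenotype *p*, linked to disease *d* — **only if five independently
curated pairwise relations all exist**:

```
chemical–gene(c,g)   chemical–phenotype(c,p)   chemical–disease(c,d)
gene–phenotype(g,p)  gene–disease(g,d)
```

Queries typically return hundreds to thousands of such tetramers as a
flat table. This package is for researchers who want to (1) run that
five-way join locally over their own curated tables, and (2) condense a
large tetramer table into a single circular diagram where the heavily
used chemicals, genes, phenotypes and diseases stand out visually.

## The transformation

Each unique tetramer is split into its three adjacent **dimers**
(C→G, G→P, P→D); dimers are tallied, so a dimer's frequency is the
number of unique tetramers containing it. A node's **weight** is the
sum of its incident dimer frequencies. On the circle:

- sector span: `span_i = (360° − n·gap) · w_i / Σw`, clockwise from
  12 o'clock in C → G → P → D order, alphabetical within a class;
- ribbon width within a sector: `span · frequency / weight`, so ribbons
  exactly tile every sector;
- colors: a per-class two-endpoint gradient (blue chemicals, green
  genes, purple phenotypes, red diseases; a colorblind-safe preset is
  included), ribbons inheriting their source sector's color.

Consequently the per-class dimer totals all equal the unique-tetramer
count, end-class nodes weigh their participation count, and middle-class
nodes weigh twice it.

## Worked example

```python
from tetrachord import compute_layout, decompose, node_weights
from tetrachord.fixtures import ozone_toy

table = decompose(ozone_toy())        # 3 tetramers: ozone -> airway obstruction
for d in table.dimers:
    print(f"{d.source.term} -> {d.target.term}  (x{d.frequency})")
for nw in node_weights(table):
    print(nw.node.term, nw.weight)
```

prints

```
Ozone -> PTGFR  (x2)
Ozone -> TFPI  (x1)
PTGFR -> inflammatory response  (x1)
PTGFR -> response to lipopolysaccharide  (x1)
TFPI -> response to lipopolysaccharide  (x1)
inflammatory response -> Airway Obstruction  (x1)
response to lipopolysaccharide -> Airway Obstruction  (x2)
Ozone 3
PTGFR 4
TFPI 2
inflammatory response 2
response to lipopolysaccharide 4
Airway Obstruction 3
```

PTGFR and "response to lipopolysaccharide" appear in two of the three
tetramers, so their weights (4) — and hence sectors — are double
TFPI's and "inflammatory response"'s (2): overrepresentation is read
directly off the diagram. `compute_layout(table)` turns the weights
into sector angles (here 78.67° for PTGFR vs 39.33° for TFPI at the
default 1° gap) and `render(...)` writes the SVG. See `examples/` for
complete scripts, including the five-way join over a curated database
and the multi-query merge.

## Command line

```bash
tetrachord generate --interactions curated.csv --out tetramers.csv
tetrachord merge q1.csv q2.csv q3.csv --out all.csv
tetrachord summarize all.csv --json
tetrachord plot all.csv --out all.svg --cex 0.5 --label-mode id
tetrachord fixtures --seed 1 --out-dir fixtures/
```

`plot` accepts several CSVs (merged by concatenation), `--gap-degree`,
`--palette class=color1,color2`, `--colorblind-safe`, a YAML `--config`,
and `--geometry-json` to dump the layout for external renderers. Sets
beyond ~1,500 tetramers trigger a readability warning (never an error);
an infeasible gap fails with the largest feasible `gap_degree` in the
message.

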