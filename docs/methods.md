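# Methods

## The tetramer model

A CGPD-tetramer is an ordered quadruple (chemical, gene, phenotype,
disease) asserted only when five independently curated pairwise
relations all exist: chemical–gene, chemical–phenotype,
chemical–disease, gene–phenotype and gene–disease. The model treats
curated interaction tables as undirected presence/absence relations on
accession pairs; curation qualifiers (organisms, action types, evidence
counts) are outside the join and carried through, when present in CSV
input, as opaque annotation columns.

Nodes are identified by `(accession, node_class)` and tetramers by
their 4-tuple of accessions. Display terms are presentation only: the
same term string may legally appear as both a gene symbol and a
chemical name without the nodes merging, and switching labels between
terms and IDs never changes any computed frequency.

### The join

`generate_tetramers` iterates chemical–gene pairs and intersects the
phenotype and disease neighbourhoods of the chemical and the gene. This
is algebraically identical to enumerating all |C|·|G|·|P|·|D| candidate
quadruples and testing the five memberships — the brute-force form kept
in `fixtures.brute_force_tetramers` as the oracle — but costs
O(|CG| · (p̄ + d̄)) instead. Output is deduplicated and sorted
case-insensitively by display terms (chemical, gene, phenotype,
disease), ties broken by accession, matching the alphabetical default
of tabular query interfaces.

Filters are per-class accession sets; an absent or empty set leaves the
class unconstrained. With descendant expansion enabled, a filter set is
replaced by its transitive closure under the class's parent→child
hierarchy, *including the roots* (a "metals" root must reach copper and
iron while remaining matchable itself). Unknown filter accessions warn
and match nothing rather than erroring, since a user's query term may
simply be absent from a local extract.

### Merge semantics

`merge_tetramer_sets` defaults to plain concatenation, because the
manual workflow it replaces — pasting separate query downloads into one
CSV — preserves duplicates; three disjoint downloads of 123, 122 and
136 rows must merge to exactly 381 records. Deduplication (first
occurrence kept) is opt-in. `summarize` reports both the row count and
the unique-tetramer count so either convention can be audited.

## Dimer decomposition and node weights

Each *unique* tetramer contributes one occurrence to each of C→G, G→P
and P→D; frequencies therefore count unique tetramers, never CSV rows,
and per-class frequency totals each equal the unique-tetramer count
(an invariant the tests enforce). A node's weight is the sum of its
incident dimer frequencies. This makes middle-class nodes (genes,
phenotypes) weigh twice their participation count while end classes
weigh it exactly — a deliberate design choice: it is the only weight
definition under which every sector is exactly tiled by its ribbons,
which is what makes the diagram read quantitatively. Describing a
node's length as "how often the term occurs" remains true up to that
factor of two within each class.

## Layout geometry

All angles are degrees. Clockwise placement is represented by
decreasing angle; a sector stores `(theta_start, theta_end)` with
`span = theta_start − theta_end > 0`, and the default start angle of
90° puts the first chemical at 12 o'clock.

- **Spans.** `span_i = (360 − n·gap_degree) · w_i / Σw`. The layout is
  feasible iff `n · gap_degree < 360`; at or beyond the bound a
  distinct error reports the supremum `360/n` so the user can pick any
  smaller gap in one step instead of iterating. No automatic gap
  shrinking is performed.
- **Order.** Classes clockwise C→G→P→D; within a class, alphabetical
  by label (case-folded, ties by accession) by default, with a
  by-weight (descending) option. Ribbons pack inside each sector in
  the clockwise order of their partner sectors, which keeps ribbons
  from the same neighbourhood adjacent and is fully deterministic.
- **Colors.** For a class of k sectors, sector i gets the linear RGB
  interpolation at i/(k−1) between the class's two palette endpoints
  (k = 1 → first endpoint). Ribbons take their source sector's color
  at a fixed opacity (default 0.6, configurable), so the three dimer
  classes read as blue, green and purple bands. Default palettes are
  light→dark blue/green/purple/red pairs; a colorblind-safe preset
  anchored on Okabe–Ito hues ships alongside. Color parsing is
  delegated to matplotlib, so names, hex and RGB tuples all work.
- **Labels.** Anchored at the sector's angular midpoint at 1.04× the
  outer radius, rotated to read radially and flipped on the left half
  so text is never upside down. Nominal font size is
  `10 px × font_scale`; `font_scale` is the classic `cex` knob
  (0.5 → 50 % smaller, 1.5 → 50 % larger) and the CLI accepts `--cex`
  as an alias. Label text is the display term or, with
  `label_mode=id`, the accession — the standard remedy for crowded
  diagrams, alongside smaller fonts.
- **Scale warning.** Above 1,500 tetramers (configurable) the layout
  attaches a warning, reflecting a practical readability ceiling for
  this diagram family; it is advisory, never a cap.

Numerical tolerances: angle conservation (Σ spans + n·gap = 360),
proportionality and ribbon tiling are all exact up to float summation
(observed residuals ~1e-13; asserted at 1e-9). There is no randomness
anywhere in layout or rendering, so identical inputs give bit-identical
geometry and bytes.

## Rendering

SVG is the source of truth. The writer emits the document directly
with all coordinates formatted at a fixed 6 decimals, giving
byte-reproducible golden files. Each sector is one annular path (outer
arc, radial edge, inner arc); each ribbon is one closed path — an arc
across its source sub-span at the inner radius, a cubic Bezier through
the interior to the target sub-span, an arc across it, and a Bezier
back. Bezier control points sit at `center + fraction · (endpoint −
center)` with fraction 0 by default, the classic through-the-center
chord shape. Tests parse the emitted XML and recover the sector angles
from arc endpoints to 1e-6 px.

PNG output draws the same layout via the matplotlib Agg backend at a
stated DPI (arcs polylined at ≥1 point/degree, ribbons as CURVE4
paths); if no raster backend can be imported a capability error is
raised rather than silently degrading. PDF export is out of scope.

The geometry also serializes to a documented JSON schema
(`tetrachord-layout/1`), usable for golden-file comparisons or external
renderers; the renderer accepts a layout rebuilt from that JSON.

## Synthetic data

The fixture generators emulate the three input families — curated
interaction tables, tetramer CSV downloads, and term hierarchies — with
integer-only RNG draws (numpy `default_rng`) so outputs are identical
across platforms for a given seed. Synthetic accessions are
`C####/G####/P####/D####`.

- `make_database` fills each of the five relation tables independently
  with probability 0.3 by default over 10 chemicals × 20 genes ×
  20 phenotypes × 5 diseases (≈10⁴ candidate quadruples, a size at
  which exhaustive enumeration is still instant), optionally planting
  complete quadruples on distinct chemicals so a zero-background spec
  yields exactly the planted count. Every database ships with its
  brute-force closure, so join tests are oracle-by-construction.
- `make_tetramer_table` draws unique quadruples uniformly without
  replacement; `make_disjoint_tables` splits one draw, guaranteeing
  disjointness (the 123/122/136 worked example); planted-overlap pairs
  support merge-arithmetic checks.
- `ozone_toy` is a reconstruction of a published three-tetramer
  schematic (ozone / PTGFR / TFPI / inflammatory response / response to
  lipopolysaccharide / airway obstruction); the original's exact rows
  are not public, so the unique composition consistent with its stated
  overrepresentation pattern is encoded and flagged as such.
- `testcsv_like` reproduces only the *shape* of a 309-tetramer
  metals/liver-neoplasms query download (2 chemicals, 61 genes,
  87 phenotypes, 1 disease, full coverage of every term); its gene and
  phenotype content is synthetic and makes no claim about the real
  file. Tests passing on it validate the CSV dialect, the summary
  arithmetic and the pipeline at realistic scale — not agreement with
  any live database's curated content, which shifts monthly anyway.

What the synthetic data does not emulate: real accession namespaces
(MeSH/NCBI/GO), curation evidence and directionality, the degree
distributions of real curated networks (real chemical–gene tables are
far more skewed than independent Bernoulli fills), and live-database
headline counts, which depend on curation state and are therefore out
of scope here.

## Problem sizes

The test suite checks the join against exhaustive enumeration on 100
seeded databases — mostly ~400-quadruple instances for breadth plus
instances up to ~10⁵ candidate quadruples — and every single-interaction
deletion on small databases; layout and rendering properties run on
tables of 60–250 tetramers and boundary cases up to 400 sectors. The
whole suite and the acceptance script each complete in seconds on one
CPU.

## Known limitations

- Label placement is nominal: no font metrics, no collision avoidance
  beyond `font_scale` and ID mode.
- The join is in-memory and single-threaded; it targets local extracts
  (up to ~10⁶ interactions), not full-database scale.
- Extra CSV annotation columns are preserved per file; writing a merged
  set unions the extra columns, padding missing cells with empty
  strings.
- Interactive display, edge bundling, multi-track circular layouts and
  tetramer ranking/enrichment statistics are out of scope.
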