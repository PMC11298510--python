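"""From a three-tetramer toy set to a rendered chord diagram.

Decomposes the tetramers into chemical->gene, gene->phenotype and
phenotype->disease dimers with support frequencies, lays out sectors
whose angular spans are proportional to node weights, and writes an
SVG plus the renderer-independent geometry JSON.
"""

from pathlib import Path

from tetrachord import (
    LayoutConfig,
    RenderSpec,
    compute_layout,
    decompose,
    layout_to_json,
    node_weights,
    render,
)
from tetrachord.fixtures import ozone_toy

toy = ozone_toy()
table = decompose(toy)
print(f"{table.n_tetramers} tetramers -> {len(table.dimers)} dimers")
for d in table.dimers:
    print(f"  {d.source.term} -> {d.target.term}  (x{d.frequency})")

# node weight = summed incident dimer frequencies; it sets sector size
print("node weights (sector sizes):")
for nw in node_weights(table):
    print(f"  {nw.node.term}: {nw.weight}")

layout = compute_layout(table, LayoutConfig(gap_degree=1.0, font_scale=1.0))
for s in layout.sectors:
    print(f"  sector {s.label}: {s.span:.2f} degrees, {s.color}")

out = Path("scratch") if Path("scratch").is_dir() else Path(".")
summary = render(layout, RenderSpec(size=800), out / "toy_chord.svg")
(out / "toy_chord.json").write_text(layout_to_json(layout))
print(f"wrote {out / 'toy_chord.svg'}: {summary.sectors} sectors, "
      f"{summary.ribbons} ribbons, {summary.labels} labels")
# The larger PTGFR and response-to-lipopolysaccharide sectors mark the
# gene and phenotype appearing in two of the three tetramers.
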