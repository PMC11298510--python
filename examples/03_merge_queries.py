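"""Combine several query downloads into one diagram.

Separate tetramer queries (here three synthetic "downloads" of 123,
122 and 136 tetramers, standing in for per-chemical queries against a
shared disease) are concatenated -- the same semantics as pasting the
CSVs together -- and plotted as a single chord diagram, after which
the shared genes and phenotypes are visible as larger sectors.
"""

from pathlib import Path

from tetrachord import (
    LayoutConfig,
    RenderSpec,
    compute_layout,
    decompose,
    merge_tetramer_sets,
    render,
    summarize,
)
from tetrachord.fixtures import make_disjoint_tables

queries = make_disjoint_tables([123, 122, 136], seed=0)
for q in queries:
    print(f"{q.source_label}: {len(q)} tetramers")

merged = merge_tetramer_sets(queries)  # plain concatenation, no dedup
print("merged:", summarize(merged).to_dict())

table = decompose(merged)
# many sectors -> shrink labels and switch to a smaller gap
layout = compute_layout(table, LayoutConfig(gap_degree=0.5, font_scale=0.4))
out = Path("scratch") if Path("scratch").is_dir() else Path(".")
summary = render(layout, RenderSpec(size=1000), out / "merged_chord.svg")
print(f"wrote {out / 'merged_chord.svg'}: {summary.sectors} sectors, "
      f"{summary.ribbons} ribbons")
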