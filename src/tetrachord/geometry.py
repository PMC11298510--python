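"""Backend-independent chord-diagram geometry.

Given a dimer table, :func:`compute_layout` places one sector (an
angular span on the circle) per node and one ribbon per dimer, with

* sector span proportional to node weight:
  ``span_i = (360 - n_sectors * gap_degree) * w_i / sum(w)``;
* sectors ordered clockwise chemical -> gene -> phenotype -> disease
  starting at 12 o'clock, alphabetically by label within a class;
* ribbon sub-spans tiling each sector exactly, width proportional to
  dimer frequency over node weight;
* per-class two-endpoint gradient palettes (blue chemicals, green
  genes, purple phenotypes, red diseases by default) with ribbons
  taking their source sector's color.

Angles are in degrees.  Clockwise placement is represented by
decreasing angle, so a sector's span is ``theta_start - theta_end > 0``
and the default ``start_angle`` of 90 puts the first chemical at
12 o'clock.  The layout is deterministic: no randomness anywhere, and
identical inputs give identical output.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from matplotlib.colors import to_hex, to_rgb

from .dimers import Dimer, DimerClass, DimerTable, node_weights
from .model import Diagnostics, NodeClass, TermRef

__all__ = [
    "LabelMode",
    "SectorOrder",
    "LayoutConfig",
    "Sector",
    "Ribbon",
    "LabelAnchor",
    "ChordLayout",
    "GapInfeasibleError",
    "EmptyTableError",
    "compute_layout",
    "assign_colors",
    "place_labels",
    "interpolate_palette",
    "DEFAULT_PALETTES",
    "COLORBLIND_SAFE_PALETTES",
    "layout_to_json",
    "layout_from_json",
]

BASE_FONT_SIZE = 10.0  # nominal label size in px at font_scale 1
DEFAULT_RIBBON_OPACITY = 0.6
LABEL_RADIUS_FRACTION = 1.04  # label anchor sits just outside the ring

# lighter -> darker endpoint pairs per class
DEFAULT_PALETTES: dict[NodeClass, tuple[str, str]] = {
    NodeClass.CHEMICAL: ("#9ecae1", "#08519c"),   # blues
    NodeClass.GENE: ("#a1d99b", "#006d2c"),       # greens
    NodeClass.PHENOTYPE: ("#bcbddc", "#54278f"),  # purples
    NodeClass.DISEASE: ("#fcae91", "#a50f15"),    # reds
}

# Okabe-Ito-anchored pairs distinguishable under common color-vision
# deficiencies; hue families still follow the blue/green/purple/red code.
COLORBLIND_SAFE_PALETTES: dict[NodeClass, tuple[str, str]] = {
    NodeClass.CHEMICAL: ("#56b4e9", "#0072b2"),
    NodeClass.GENE: ("#90c987", "#117733"),
    NodeClass.PHENOTYPE: ("#cc79a7", "#882255"),
    NodeClass.DISEASE: ("#e69f00", "#d55e00"),
}


class LabelMode(enum.Enum):
    TERM = "term"
    ID = "id"


class SectorOrder(enum.Enum):
    ALPHABETICAL = "alphabetical"
    WEIGHT = "weight"


class GapInfeasibleError(ValueError):
    """Sector gaps alone would meet or exceed the full circle.

    Mirrors the classic circular-layout failure "no space to allocate
    sectors"; ``largest_feasible_gap`` is the exclusive upper bound
    360 / n_sectors, so any gap_degree strictly below it succeeds.
    """

    def __init__(self, n_sectors: int, gap_degree: float):
        self.n_sectors = n_sectors
        self.gap_degree = gap_degree
        self.largest_feasible_gap = 360.0 / n_sectors
        super().__init__(
            f"gap_degree={gap_degree:g} is too large for {n_sectors} sectors: "
            f"no space left to allocate sectors; choose gap_degree < "
            f"{self.largest_feasible_gap:g}"
        )


class EmptyTableError(ValueError):
    """The dimer table holds no dimers, so there is nothing to lay out."""


@dataclass(frozen=True)
class LayoutConfig:
    """Tunable layout parameters.

    gap_degree
        Angular gap between adjacent sectors, degrees (default 1).
    start_angle
        Where the first chemical sector begins; 90 = 12 o'clock.
    label_mode
        ``term`` shows display names, ``id`` shows accessions.
    font_scale
        Multiplicative label-size factor (the classic ``cex``),
        default 1.
    palettes
        Per-class (first, second) color endpoints; a gradient is built
        from the first color to the second across the class's sectors.
    ribbon_opacity
        Fill opacity of ribbons, 0-1.
    sector_order
        Within-class ordering, alphabetical (default) or by weight
        (descending).
    tetramer_warn_limit
        Emit a diagnostics warning (never an error) above this many
        tetramers; very large sets make for unreadable diagrams.
    """

    gap_degree: float = 1.0
    start_angle: float = 90.0
    label_mode: LabelMode = LabelMode.TERM
    font_scale: float = 1.0
    palettes: dict[NodeClass, tuple[str, str]] = field(
        default_factory=lambda: dict(DEFAULT_PALETTES)
    )
    ribbon_opacity: float = DEFAULT_RIBBON_OPACITY
    sector_order: SectorOrder = SectorOrder.ALPHABETICAL
    tetramer_warn_limit: int = 1500

    def __post_init__(self) -> None:
        if self.gap_degree < 0:
            raise ValueError("gap_degree must be >= 0")
        if self.font_scale <= 0:
            raise ValueError("font_scale must be > 0")
        if len(self.palettes) != 4:
            raise ValueError("palettes must provide all four node classes")


@dataclass(frozen=True)
class LabelAnchor:
    angle: float          # degrees, sector midpoint
    radius: float         # fraction of outer radius
    rotation: float       # degrees, radially-readable text rotation
    text: str
    font_size: float      # nominal px


@dataclass
class Sector:
    node: TermRef
    weight: int
    theta_start: float
    theta_end: float
    color: str = "#000000"
    label: str = ""
    anchor: Optional[LabelAnchor] = None

    @property
    def span(self) -> float:
        return self.theta_start - self.theta_end

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.theta_start + self.theta_end)


@dataclass
class Ribbon:
    dimer: Dimer
    source_span: tuple[float, float]  # (theta_start, theta_end), start > end
    target_span: tuple[float, float]
    color: str = "#000000"
    opacity: float = DEFAULT_RIBBON_OPACITY


@dataclass
class ChordLayout:
    sectors: list[Sector]
    ribbons: list[Ribbon]
    config: LayoutConfig
    diagnostics: Diagnostics = field(default_factory=Diagnostics)

    def sector_for(self, node_key: tuple[str, str]) -> Sector:
        for s in self.sectors:
            if s.node.key == node_key:
                return s
        raise KeyError(node_key)


def interpolate_palette(endpoints: tuple[str, str], k: int) -> list[str]:
    """k colors linearly interpolated between the two endpoints.

    Sector i (0-indexed) gets the interpolation at ``i / (k - 1)``; a
    single sector gets the first endpoint exactly.  Color names are
    parsed with matplotlib, so anything it accepts works; an
    unparsable entry raises a ValueError naming it.
    """
    rgb = []
    for name in endpoints:
        try:
            rgb.append(to_rgb(name))
        except ValueError as exc:
            raise ValueError(f"unparsable color {name!r}") from exc
    (r0, g0, b0), (r1, g1, b1) = rgb
    if k == 1:
        return [to_hex((r0, g0, b0))]
    out = []
    for i in range(k):
        f = i / (k - 1)
        out.append(to_hex((r0 + f * (r1 - r0),
                           g0 + f * (g1 - g0),
                           b0 + f * (b1 - b0))))
    return out


def _label_text(node: TermRef, mode: LabelMode) -> str:
    return node.accession if mode is LabelMode.ID else node.term


def compute_layout(table: DimerTable, config: LayoutConfig = LayoutConfig()
                   ) -> ChordLayout:
    """Full layout: sectors, ribbons, colors and label anchors.

    Raises :class:`GapInfeasibleError` when
    ``n_sectors * gap_degree >= 360`` and :class:`EmptyTableError` on an
    empty table.  Emits a warning (not an error) when the table derives
    from more than ``config.tetramer_warn_limit`` tetramers.
    """
    if not table.dimers:
        raise EmptyTableError("dimer table is empty; nothing to lay out")

    diagnostics = Diagnostics()
    if table.n_tetramers > config.tetramer_warn_limit:
        diagnostics.warn(
            f"{table.n_tetramers} tetramers exceed the practical "
            f"readability limit of {config.tetramer_warn_limit}; consider "
            "narrowing the query, lowering font_scale, or label_mode=id"
        )

    weights = node_weights(table)
    by_class: dict[NodeClass, list] = {c: [] for c in NodeClass}
    for nw in weights:
        by_class[nw.node.node_class].append(nw)

    ordered = []
    for node_class in NodeClass:
        group = by_class[node_class]
        if config.sector_order is SectorOrder.WEIGHT:
            group.sort(key=lambda nw: (-nw.weight,
                                       _label_text(nw.node, config.label_mode)
                                       .casefold(),
                                       nw.node.accession))
        else:
            group.sort(key=lambda nw: (_label_text(nw.node, config.label_mode)
                                       .casefold(),
                                       nw.node.accession))
        ordered.extend(group)

    n = len(ordered)
    if n * config.gap_degree >= 360.0:
        raise GapInfeasibleError(n, config.gap_degree)

    total_weight = sum(nw.weight for nw in ordered)
    available = 360.0 - n * config.gap_degree

    sectors: list[Sector] = []
    cursor = config.start_angle
    for nw in ordered:
        span = available * nw.weight / total_weight
        sectors.append(Sector(
            node=nw.node,
            weight=nw.weight,
            theta_start=cursor,
            theta_end=cursor - span,
            label=_label_text(nw.node, config.label_mode),
        ))
        cursor -= span + config.gap_degree

    index = {s.node.key: i for i, s in enumerate(sectors)}

    # Pack ribbons: for each sector, incident dimers ordered by the
    # partner sector's clockwise position (ties cannot arise: one dimer
    # per partner per class), allocated from theta_start clockwise.
    incident: dict[int, list[Dimer]] = {i: [] for i in range(n)}
    for d in table.dimers:
        incident[index[d.source.key]].append(d)
        incident[index[d.target.key]].append(d)

    spans: dict[tuple[tuple[str, str, str], int], tuple[float, float]] = {}
    for i, sec in enumerate(sectors):
        def partner_pos(d: Dimer) -> tuple[int, str]:
            other = d.target if index[d.source.key] == i else d.source
            return (index[other.key], other.accession)

        incident[i].sort(key=partner_pos)
        cur = sec.theta_start
        for d in incident[i]:
            width = sec.span * d.frequency / sec.weight
            spans[(d.key, i)] = (cur, cur - width)
            cur -= width

    ribbons = [
        Ribbon(
            dimer=d,
            source_span=spans[(d.key, index[d.source.key])],
            target_span=spans[(d.key, index[d.target.key])],
            opacity=config.ribbon_opacity,
        )
        for d in table.dimers
    ]

    layout = ChordLayout(sectors=sectors, ribbons=ribbons, config=config,
                         diagnostics=diagnostics)
    assign_colors(layout, config.palettes)
    place_labels(layout, config)
    return layout


def assign_colors(layout: ChordLayout,
                  palettes: Optional[dict[NodeClass, tuple[str, str]]] = None
                  ) -> ChordLayout:
    """Color sectors by per-class gradient; ribbons take the source color.

    Within a class of k sectors, sector i (in layout order) gets the
    linear interpolation at i/(k-1) between the class's two endpoint
    colors, so chemical->gene ribbons read blue, gene->phenotype green
    and phenotype->disease purple under the default palettes.
    """
    palettes = palettes or layout.config.palettes
    for node_class in NodeClass:
        group = [s for s in layout.sectors if s.node.node_class is node_class]
        if not group:
            continue
        colors = interpolate_palette(palettes[node_class], len(group))
        for s, c in zip(group, colors):
            s.color = c
    by_key = {s.node.key: s for s in layout.sectors}
    for r in layout.ribbons:
        r.color = by_key[r.dimer.source.key].color
    return layout


def place_labels(layout: ChordLayout,
                 config: Optional[LayoutConfig] = None) -> ChordLayout:
    """Anchor each label at its sector midpoint, radially readable.

    The nominal font size is ``BASE_FONT_SIZE * font_scale``; text on
    the left half of the circle is flipped 180 degrees so it never
    reads upside down.
    """
    config = config or layout.config
    for s in layout.sectors:
        mid = s.midpoint
        # screen rotation for radial text (y-down SVG coordinates)
        rot = -mid % 360.0
        if 90.0 < rot <= 270.0:
            rot = (rot + 180.0) % 360.0
        layout_text = _label_text(s.node, config.label_mode)
        s.label = layout_text
        s.anchor = LabelAnchor(
            angle=mid,
            radius=LABEL_RADIUS_FRACTION,
            rotation=rot,
            text=layout_text,
            font_size=BASE_FONT_SIZE * config.font_scale,
        )
    return layout


# ---------------------------------------------------------------------------
# JSON geometry dump: a documented, renderer-independent serialization.

def layout_to_json(layout: ChordLayout, indent: int = 2) -> str:
    """Serialize a layout to the JSON geometry schema (stable key order)."""
    doc = {
        "schema": "tetrachord-layout/1",
        "config": {
            "gap_degree": layout.config.gap_degree,
            "start_angle": layout.config.start_angle,
            "label_mode": layout.config.label_mode.value,
            "font_scale": layout.config.font_scale,
            "ribbon_opacity": layout.config.ribbon_opacity,
            "sector_order": layout.config.sector_order.value,
        },
        "sectors": [
            {
                "term": s.node.term,
                "accession": s.node.accession,
                "node_class": s.node.node_class.value,
                "weight": s.weight,
                "theta_start": s.theta_start,
                "theta_end": s.theta_end,
                "color": s.color,
                "label": s.label,
                "anchor": None if s.anchor is None else {
                    "angle": s.anchor.angle,
                    "radius": s.anchor.radius,
                    "rotation": s.anchor.rotation,
                    "text": s.anchor.text,
                    "font_size": s.anchor.font_size,
                },
            }
            for s in layout.sectors
        ],
        "ribbons": [
            {
                "dimer_class": r.dimer.dimer_class.value,
                "source_accession": r.dimer.source.accession,
                "target_accession": r.dimer.target.accession,
                "frequency": r.dimer.frequency,
                "source_span": list(r.source_span),
                "target_span": list(r.target_span),
                "color": r.color,
                "opacity": r.opacity,
            }
            for r in layout.ribbons
        ],
        "diagnostics": list(layout.diagnostics.warnings),
    }
    return json.dumps(doc, indent=indent, sort_keys=False)


def layout_from_json(text: str) -> ChordLayout:
    """Rebuild a renderable layout from the JSON geometry schema."""
    doc = json.loads(text)
    if doc.get("schema") != "tetrachord-layout/1":
        raise ValueError("not a tetrachord layout document")
    cfg = doc["config"]
    config = LayoutConfig(
        gap_degree=cfg["gap_degree"],
        start_angle=cfg["start_angle"],
        label_mode=LabelMode(cfg["label_mode"]),
        font_scale=cfg["font_scale"],
        ribbon_opacity=cfg["ribbon_opacity"],
        sector_order=SectorOrder(cfg["sector_order"]),
    )
    sectors = []
    for sd in doc["sectors"]:
        node = TermRef(term=sd["term"], accession=sd["accession"],
                       node_class=NodeClass(sd["node_class"]))
        anchor = sd.get("anchor")
        sectors.append(Sector(
            node=node, weight=sd["weight"],
            theta_start=sd["theta_start"], theta_end=sd["theta_end"],
            color=sd["color"], label=sd["label"],
            anchor=None if anchor is None else LabelAnchor(
                angle=anchor["angle"], radius=anchor["radius"],
                rotation=anchor["rotation"], text=anchor["text"],
                font_size=anchor["font_size"],
            ),
        ))
    by_key = {(s.node.accession, s.node.node_class.value): s.node
              for s in sectors}
    ribbons = []
    for rd in doc["ribbons"]:
        dclass = DimerClass(rd["dimer_class"])
        src = by_key[(rd["source_accession"], dclass.source_class.value)]
        tgt = by_key[(rd["target_accession"], dclass.target_class.value)]
        ribbons.append(Ribbon(
            dimer=Dimer(dimer_class=dclass, source=src, target=tgt,
                        frequency=rd["frequency"]),
            source_span=tuple(rd["source_span"]),
            target_span=tuple(rd["target_span"]),
            color=rd["color"], opacity=rd["opacity"],
        ))
    diagnostics = Diagnostics(warnings=list(doc.get("diagnostics", [])))
    return ChordLayout(sectors=sectors, ribbons=ribbons, config=config,
                       diagnostics=diagnostics)
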