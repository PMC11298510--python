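"""Render a :class:`~tetrachord.geometry.ChordLayout` to SVG or PNG.

The SVG backend emits the document directly with fixed 6-decimal
coordinate formatting, so identical layouts always produce
byte-identical files.  Each sector becomes one annular-sector path,
each ribbon one closed path made of the two sector-edge arcs joined by
cubic Bezier curves whose control points are pulled toward the circle
center (control fraction 0 routes them through the center, the classic
chord look), and each label one rotated text element.

PNG output draws the same geometry with the matplotlib Agg backend at
a configurable DPI; the SVG path is the geometric source of truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Union
from xml.sax.saxutils import escape

from .geometry import ChordLayout, Ribbon, Sector

__all__ = ["RenderSpec", "RenderSummary", "RasterUnavailableError",
           "render", "render_svg", "render_png"]


class RasterUnavailableError(RuntimeError):
    """PNG output requested but no raster backend is importable."""


@dataclass(frozen=True)
class RenderSpec:
    """Canvas and shape parameters for rendering.

    Radii are fractions of half the canvas size; the ribbon control
    fraction sets how far Bezier control points sit from the center
    (0 = exactly at the center).
    """

    size: int = 800
    outer_radius_fraction: float = 0.80
    ring_thickness_fraction: float = 0.06
    ribbon_control_fraction: float = 0.0
    background: str = "#ffffff"
    output_format: str = "svg"  # "svg" | "png"
    dpi: int = 100

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("canvas size must be positive")
        for name in ("outer_radius_fraction", "ring_thickness_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if not 0 <= self.ribbon_control_fraction <= 1:
            raise ValueError("ribbon_control_fraction must lie in [0, 1]")
        if self.output_format not in ("svg", "png"):
            raise ValueError("output_format must be 'svg' or 'png'")


@dataclass(frozen=True)
class RenderSummary:
    sectors: int
    ribbons: int
    labels: int


def _fmt(v: float) -> str:
    s = f"{v:.6f}"
    return "0.000000" if s == "-0.000000" else s


class _Canvas:
    """Angle/radius to pixel conversion; y grows downward in SVG."""

    def __init__(self, spec: RenderSpec):
        self.c = spec.size / 2.0
        half = spec.size / 2.0
        self.r_out = half * spec.outer_radius_fraction
        self.r_in = self.r_out * (1.0 - spec.ring_thickness_fraction)
        self.r_label = self.r_out * 1.04

    def point(self, theta_deg: float, r: float) -> tuple[float, float]:
        th = math.radians(theta_deg)
        return (self.c + r * math.cos(th), self.c - r * math.sin(th))


def _arc(cv: _Canvas, r: float, theta_from: float, theta_to: float,
         sweep_cw: bool) -> str:
    """SVG arc command from the current point to angle ``theta_to``.

    In our convention decreasing theta is clockwise on screen, which is
    SVG sweep flag 1 (y axis points down).
    """
    x, y = cv.point(theta_to, r)
    large = 1 if abs(theta_from - theta_to) > 180.0 else 0
    sweep = 1 if sweep_cw else 0
    return f"A {_fmt(r)} {_fmt(r)} 0 {large} {sweep} {_fmt(x)} {_fmt(y)}"


def _sector_path(cv: _Canvas, s: Sector) -> str:
    x0, y0 = cv.point(s.theta_start, cv.r_out)
    x1, y1 = cv.point(s.theta_end, cv.r_in)
    return " ".join([
        f"M {_fmt(x0)} {_fmt(y0)}",
        _arc(cv, cv.r_out, s.theta_start, s.theta_end, sweep_cw=True),
        f"L {_fmt(x1)} {_fmt(y1)}",
        _arc(cv, cv.r_in, s.theta_end, s.theta_start, sweep_cw=False),
        "Z",
    ])


def _bezier(cv: _Canvas, frac: float, theta_from: float,
            theta_to: float) -> str:
    """Cubic through the interior, control points pulled toward center."""
    x0, y0 = cv.point(theta_from, cv.r_in)
    x1, y1 = cv.point(theta_to, cv.r_in)
    c1 = (cv.c + (x0 - cv.c) * frac, cv.c + (y0 - cv.c) * frac)
    c2 = (cv.c + (x1 - cv.c) * frac, cv.c + (y1 - cv.c) * frac)
    return (f"C {_fmt(c1[0])} {_fmt(c1[1])} "
            f"{_fmt(c2[0])} {_fmt(c2[1])} {_fmt(x1)} {_fmt(y1)}")


def _ribbon_path(cv: _Canvas, r: Ribbon, control_fraction: float) -> str:
    (s0, s1), (t0, t1) = r.source_span, r.target_span
    x, y = cv.point(s0, cv.r_in)
    return " ".join([
        f"M {_fmt(x)} {_fmt(y)}",
        _arc(cv, cv.r_in, s0, s1, sweep_cw=True),     # across source span
        _bezier(cv, control_fraction, s1, t0),         # interior to target
        _arc(cv, cv.r_in, t0, t1, sweep_cw=True),      # across target span
        _bezier(cv, control_fraction, t1, s0),         # interior back
        "Z",
    ])


def render_svg(layout: ChordLayout, spec: RenderSpec = RenderSpec()
               ) -> tuple[str, RenderSummary]:
    """Build the SVG document string and an element-count summary."""
    cv = _Canvas(spec)
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{spec.size}" height="{spec.size}" '
        f'viewBox="0 0 {spec.size} {spec.size}">',
        f'<rect width="{spec.size}" height="{spec.size}" '
        f'fill="{spec.background}"/>',
        '<g class="ribbons">',
    ]
    for r in layout.ribbons:
        lines.append(
            f'<path class="ribbon" d="{_ribbon_path(cv, r, spec.ribbon_control_fraction)}" '
            f'fill="{r.color}" fill-opacity="{_fmt(r.opacity)}" stroke="none"/>'
        )
    lines.append("</g>")
    lines.append('<g class="sectors">')
    for s in layout.sectors:
        lines.append(
            f'<path class="sector" d="{_sector_path(cv, s)}" '
            f'fill="{s.color}" stroke="none"/>'
        )
    lines.append("</g>")
    lines.append('<g class="labels">')
    n_labels = 0
    for s in layout.sectors:
        if s.anchor is None:
            continue
        x, y = cv.point(s.anchor.angle, cv.r_out * s.anchor.radius)
        rot = s.anchor.rotation
        # flipped labels (left half of the circle) anchor at their end
        # so the text still points away from the ring
        flipped = 90.0 < (-s.anchor.angle) % 360.0 <= 270.0
        anchor_side = "end" if flipped else "start"
        lines.append(
            f'<text class="label" x="{_fmt(x)}" y="{_fmt(y)}" '
            f'font-size="{_fmt(s.anchor.font_size)}" '
            f'text-anchor="{anchor_side}" '
            f'transform="rotate({_fmt(rot)} {_fmt(x)} {_fmt(y)})">'
            f'{escape(s.anchor.text)}</text>'
        )
        n_labels += 1
    lines.append("</g>")
    lines.append("</svg>")
    summary = RenderSummary(sectors=len(layout.sectors),
                            ribbons=len(layout.ribbons), labels=n_labels)
    return "\n".join(lines) + "\n", summary


def render_png(layout: ChordLayout, spec: RenderSpec,
               sink: Union[str, Path, IO[bytes]]) -> RenderSummary:
    """Draw the layout with matplotlib Agg and write a PNG."""
    try:
        import matplotlib
        matplotlib.use("Agg", force=False)
        from matplotlib import pyplot as plt
        from matplotlib.patches import PathPatch, Wedge
        from matplotlib.path import Path as MplPath
    except ImportError as exc:  # pragma: no cover - matplotlib is a hard dep
        raise RasterUnavailableError(
            "PNG output needs matplotlib with the Agg backend"
        ) from exc

    cv = _Canvas(spec)
    size_in = spec.size / spec.dpi
    fig = plt.figure(figsize=(size_in, size_in), dpi=spec.dpi)
    ax = fig.add_axes([0, 0, 1, 1])
    ax.set_xlim(0, spec.size)
    ax.set_ylim(spec.size, 0)  # match SVG's y-down coordinates
    ax.axis("off")
    fig.patch.set_facecolor(spec.background)

    def arc_points(r: float, a: float, b: float) -> list[tuple[float, float]]:
        steps = max(8, int(abs(a - b)) + 1)
        return [cv.point(a + (b - a) * i / steps, r) for i in range(steps + 1)]

    for r in layout.ribbons:
        (s0, s1), (t0, t1) = r.source_span, r.target_span
        verts: list[tuple[float, float]] = []
        codes: list[int] = []
        src_arc = arc_points(cv.r_in, s0, s1)
        verts.extend(src_arc)
        codes.extend([MplPath.MOVETO] + [MplPath.LINETO] * (len(src_arc) - 1))
        frac = spec.ribbon_control_fraction
        p0, p1 = cv.point(s1, cv.r_in), cv.point(t0, cv.r_in)
        c1 = (cv.c + (p0[0] - cv.c) * frac, cv.c + (p0[1] - cv.c) * frac)
        c2 = (cv.c + (p1[0] - cv.c) * frac, cv.c + (p1[1] - cv.c) * frac)
        verts.extend([c1, c2, p1])
        codes.extend([MplPath.CURVE4] * 3)
        tgt_arc = arc_points(cv.r_in, t0, t1)[1:]
        verts.extend(tgt_arc)
        codes.extend([MplPath.LINETO] * len(tgt_arc))
        q0, q1 = cv.point(t1, cv.r_in), cv.point(s0, cv.r_in)
        c3 = (cv.c + (q0[0] - cv.c) * frac, cv.c + (q0[1] - cv.c) * frac)
        c4 = (cv.c + (q1[0] - cv.c) * frac, cv.c + (q1[1] - cv.c) * frac)
        verts.extend([c3, c4, q1])
        codes.extend([MplPath.CURVE4] * 3)
        codes.append(MplPath.CLOSEPOLY)
        verts.append(verts[0])
        ax.add_patch(PathPatch(MplPath(verts, codes), facecolor=r.color,
                               alpha=r.opacity, edgecolor="none"))

    for s in layout.sectors:
        # Wedge angles are CCW in data coordinates; our axis is y-down,
        # so pass (-start, -end) to sweep the sector clockwise on screen
        ax.add_patch(Wedge((cv.c, cv.c), cv.r_out,
                           -s.theta_start, -s.theta_end,
                           width=cv.r_out - cv.r_in,
                           facecolor=s.color, edgecolor="none"))

    n_labels = 0
    for s in layout.sectors:
        if s.anchor is None:
            continue
        x, y = cv.point(s.anchor.angle, cv.r_out * s.anchor.radius)
        ax.text(x, y, s.anchor.text, rotation=-s.anchor.rotation,
                rotation_mode="anchor", fontsize=s.anchor.font_size,
                ha="left", va="center")
        n_labels += 1

    fig.savefig(sink, format="png", dpi=spec.dpi,
                facecolor=spec.background)
    plt.close(fig)
    return RenderSummary(sectors=len(layout.sectors),
                         ribbons=len(layout.ribbons), labels=n_labels)


def render(layout: ChordLayout, spec: RenderSpec = RenderSpec(),
           sink: Union[str, Path, IO] = None) -> RenderSummary:
    """Render ``layout`` per ``spec.output_format`` into ``sink``."""
    if sink is None:
        raise ValueError("render needs a sink (path or file object)")
    if spec.output_format == "png":
        return render_png(layout, spec, sink)
    text, summary = render_svg(layout, spec)
    if isinstance(sink, (str, Path)):
        Path(sink).write_text(text, encoding="utf-8")
    else:
        sink.write(text)
    return summary
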