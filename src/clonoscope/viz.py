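"""Pure-data visual encodings of lineage trees and colony glyphs.

Lineage trees are drawn as polylines (time on one axis, lineage layout on
the other) whose width tracks the cell's spread area at each frame and whose
colour encodes generation.  Colony glyphs show each cell as a filled circle
(radius proportional to the square root of its spread area, colour by
generation, a '/' mark for senescent cells) surrounded by one ring per
originating progeny whose line style encodes proliferative class: dashed for
slow, dotted for moderate, solid for fast.

The specs hold drawable primitives only; a thin adapter renders them to SVG
so the core stays plotting-library-agnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .lineage import LineageForest

RING_STYLE = {"slow": "dashed", "moderate": "dotted", "fast": "solid"}

GENERATION_COLORS = (
    "#4c72b0", "#dd8452", "#55a868", "#c44e52", "#8172b3",
    "#937860", "#da8bc3", "#8c8c8c", "#ccb974", "#64b5cd",
)


def generation_color(generation: int) -> str:
    return GENERATION_COLORS[(generation - 1) % len(GENERATION_COLORS)]


@dataclass
class TreePolyline:
    cell_id: str
    generation: int
    color: str
    points: list[tuple[float, float]]  # (frame, layout position)
    widths: list[float]  # area-proportional line width per point


@dataclass
class TreeSpec:
    polylines: list[TreePolyline]
    branch_points: list[tuple[float, float]]  # (frame, layout position)


def render_tree(
    f: LineageForest, areas: Mapping[str, Sequence[float]] | None = None
) -> TreeSpec:
    """Lineage-tree drawing spec: one polyline per cell, leaves evenly spaced.

    ``areas`` maps cell ids to per-frame spread areas (one value per frame of
    the cell's existence); widths are the square roots of the areas so drawn
    line area tracks spread area.  Without areas all widths are 1.
    """
    # leaf layout: depth-first order, evenly spaced; parents midway
    pos: dict[str, float] = {}
    next_slot = [0.0]

    def place(cid: str) -> float:
        kids = f.records[cid].children
        if not kids:
            pos[cid] = next_slot[0]
            next_slot[0] += 1.0
        else:
            pos[cid] = (place(kids[0]) + place(kids[1])) / 2.0
        return pos[cid]

    for root in f.roots:
        place(root)
        next_slot[0] += 1.0  # gap between trees

    polylines = []
    branch_points = []
    for cid in sorted(f.records):
        rec = f.records[cid]
        frames = list(range(rec.birth_frame, rec.last_frame + 1))
        if areas and cid in areas:
            widths = [math.sqrt(max(a, 0.0)) for a in areas[cid]]
        else:
            widths = [1.0] * len(frames)
        polylines.append(
            TreePolyline(
                cell_id=cid,
                generation=rec.generation,
                color=generation_color(rec.generation),
                points=[(float(t), pos[cid]) for t in frames],
                widths=widths,
            )
        )
        if rec.divided:
            branch_points.append((float(rec.last_frame), pos[cid]))
    return TreeSpec(polylines=polylines, branch_points=branch_points)


@dataclass
class GlyphCircle:
    cell_id: str
    x: float
    y: float
    radius: float
    generation: int
    color: str
    senescent: bool  # drawn with the '/' mark


@dataclass
class GlyphRing:
    progeny_id: str
    style: str  # 'dashed' | 'dotted' | 'solid'
    radius: float


@dataclass
class GlyphSpec:
    circles: list[GlyphCircle]
    rings: list[GlyphRing]
    center: tuple[float, float] = (0.0, 0.0)


def render_glyph(
    positions: Mapping[str, tuple[float, float]],
    areas: Mapping[str, float],
    generations: Mapping[str, int],
    senescent: Mapping[str, bool] | None = None,
    progeny_classes: Mapping[str, str] | None = None,
) -> GlyphSpec:
    """Colony glyph spec for one frame snapshot.

    One circle per living cell (radius = sqrt(area / pi)) and one outer ring
    per originating progeny, styled by proliferative class.
    """
    senescent = senescent or {}
    circles = []
    for cid in sorted(positions):
        x, y = positions[cid]
        circles.append(
            GlyphCircle(
                cell_id=cid,
                x=float(x),
                y=float(y),
                radius=math.sqrt(max(areas[cid], 0.0) / math.pi),
                generation=generations[cid],
                color=generation_color(generations[cid]),
                senescent=bool(senescent.get(cid, False)),
            )
        )
    cx = float(np.mean([c.x for c in circles])) if circles else 0.0
    cy = float(np.mean([c.y for c in circles])) if circles else 0.0
    r_max = max(
        (math.hypot(c.x - cx, c.y - cy) + c.radius for c in circles),
        default=1.0,
    )
    rings = []
    for i, (pid, cls) in enumerate(sorted((progeny_classes or {}).items())):
        rings.append(
            GlyphRing(
                progeny_id=pid,
                style=RING_STYLE[cls],
                radius=r_max * (1.1 + 0.08 * i),
            )
        )
    return GlyphSpec(circles=circles, rings=rings, center=(cx, cy))


_DASH = {"dashed": "8,6", "dotted": "2,4", "solid": None}


def tree_to_svg(spec: TreeSpec, path: str | Path, width: int = 800,
                height: int = 600) -> None:
    xs = [p[0] for pl in spec.polylines for p in pl.points] or [0, 1]
    ys = [p[1] for pl in spec.polylines for p in pl.points] or [0, 1]
    x0, x1 = min(xs), max(xs) or 1
    y0, y1 = min(ys), max(ys)

    def sx(x):
        return 20 + (x - x0) / max(x1 - x0, 1e-9) * (width - 40)

    def sy(y):
        return 20 + (y - y0) / max(y1 - y0, 1e-9) * (height - 40)

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{height}">'
    ]
    for pl in spec.polylines:
        pts = " ".join(f"{sx(x):.1f},{sy(y):.1f}" for x, y in pl.points)
        w = max(0.5, float(np.mean(pl.widths)) * 0.05)
        parts.append(
            f'<polyline points="{pts}" fill="none" stroke="{pl.color}" '
            f'stroke-width="{w:.2f}"/>'
        )
        # vertical connector to the children at the division frame
    for bx, by in spec.branch_points:
        parts.append(
            f'<circle cx="{sx(bx):.1f}" cy="{sy(by):.1f}" r="2" fill="#222"/>'
        )
    parts.append("</svg>")
    Path(path).write_text("\n".join(parts), encoding="utf-8")


def glyph_to_svg(spec: GlyphSpec, path: str | Path, size: int = 600) -> None:
    cx, cy = spec.center
    r_out = max((r.radius for r in spec.rings), default=None) or max(
        (math.hypot(c.x - cx, c.y - cy) + c.radius for c in spec.circles),
        default=1.0,
    )
    scale = (size / 2 - 10) / max(r_out, 1e-9)

    def sx(x):
        return size / 2 + (x - cx) * scale

    def sy(y):
        return size / 2 + (y - cy) * scale

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{size}" '
        f'height="{size}">'
    ]
    for c in spec.circles:
        parts.append(
            f'<circle cx="{sx(c.x):.1f}" cy="{sy(c.y):.1f}" '
            f'r="{max(c.radius * scale, 1):.1f}" fill="{c.color}"/>'
        )
        if c.senescent:
            r = max(c.radius * scale, 1)
            parts.append(
                f'<line x1="{sx(c.x) - r:.1f}" y1="{sy(c.y) + r:.1f}" '
                f'x2="{sx(c.x) + r:.1f}" y2="{sy(c.y) - r:.1f}" '
                'stroke="#000" stroke-width="1.5"/>'
            )
    for ring in spec.rings:
        dash = _DASH[ring.style]
        dash_attr = f' stroke-dasharray="{dash}"' if dash else ""
        parts.append(
            f'<circle cx="{size / 2}" cy="{size / 2}" '
            f'r="{ring.radius * scale:.1f}" fill="none" stroke="#333"'
            f'{dash_attr}/>'
        )
    parts.append("</svg>")
    Path(path).write_text("\n".join(parts), encoding="utf-8")
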