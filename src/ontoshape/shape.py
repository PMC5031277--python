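"""Sub-hierarchy shape: distributions, per-sub-hierarchy errors, RSS, treemaps.

The *shape* of a class set is its vector of relative class frequencies per
sub-hierarchy, expressed in percent.  Comparing a module's shape against the
source terminology's yields a signed error per sub-hierarchy (percentage
points) and a single residual-sum-of-squares figure::

    RSS = (1/K) * sum_k Error(SH_k)^2

with K the number of sub-hierarchies of the reference.  Working in percentage
points makes the conventional convergence threshold RSS < 1 meaningful: it is
an RMS error below one percentage point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .errors import ArgumentError
from .model import OntologyGraph


@dataclass(frozen=True)
class ShapeProfile:
    """Per-sub-hierarchy class counts of some class set."""

    counts: Mapping[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def freqs(self) -> dict[str, float]:
        """Relative frequencies in percent; empty when the total is zero."""
        t = self.total
        if t == 0:
            return {}
        return {k: 100.0 * c / t for k, c in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        freqs = self.freqs
        return pd.DataFrame(
            {
                "subhierarchy": sorted(self.counts),
                "count": [self.counts[k] for k in sorted(self.counts)],
                "freq_pct": [freqs.get(k, float("nan")) for k in sorted(self.counts)],
            }
        )


@dataclass(frozen=True)
class ErrorVector:
    """Signed shape errors (percentage points) plus their RSS."""

    errors: Mapping[str, float]
    rss: float

    @property
    def max_abs(self) -> float:
        return max((abs(v) for v in self.errors.values()), default=0.0)


def profile(graph: OntologyGraph, subset: Iterable[str] | None = None) -> ShapeProfile:
    """Count classes per sub-hierarchy (root excluded).

    ``subset`` defaults to all classes; sub-hierarchies of the graph without
    members in the subset appear with count 0.
    """
    sh_of = graph.subhierarchy_of
    counts = {sh: 0 for sh in graph.subhierarchies()}
    if subset is None:
        members: Iterable[str] = sh_of
    else:
        members = []
        for cid in subset:
            if cid == graph.root:
                continue
            if cid not in graph.classes:
                raise ArgumentError(f"subset contains unknown class {cid!r}")
            members.append(cid)
    for cid in members:
        counts[sh_of[cid]] += 1
    return ShapeProfile(counts)


def rss(errors: Mapping[str, float], k: int) -> float:
    """Mean of squared errors over ``k`` sub-hierarchies; absentees count 0."""
    if k < 1:
        raise ArgumentError("k must be >= 1")
    if len(errors) > k:
        raise ArgumentError(f"{len(errors)} error entries but k = {k}")
    return sum(e * e for e in errors.values()) / k


def shape_error(
    module_profile: ShapeProfile, reference_profile: ShapeProfile
) -> ErrorVector:
    """Module minus reference frequency, per sub-hierarchy, in points.

    A sub-hierarchy of the reference absent from the module counts as 0 %.
    """
    if module_profile.total == 0:
        raise ArgumentError("module profile is empty")
    if reference_profile.total == 0:
        raise ArgumentError("reference profile is empty")
    extra = set(module_profile.counts) - set(reference_profile.counts)
    if extra:
        raise ArgumentError(
            "module sub-hierarchies not in reference: " + ", ".join(sorted(extra))
        )
    mf = module_profile.freqs
    rf = reference_profile.freqs
    errors = {k: mf.get(k, 0.0) - rf[k] for k in reference_profile.counts}
    return ErrorVector(errors, rss(errors, len(reference_profile.counts)))


def error_frame(module_profile: ShapeProfile, reference_profile: ShapeProfile) -> pd.DataFrame:
    """CSV-ready table: subhierarchy, count, freq_pct, error_pct."""
    ev = shape_error(module_profile, reference_profile)
    keys = sorted(reference_profile.counts)
    mf = module_profile.freqs
    return pd.DataFrame(
        {
            "subhierarchy": keys,
            "count": [module_profile.counts.get(k, 0) for k in keys],
            "freq_pct": [mf.get(k, 0.0) for k in keys],
            "error_pct": [ev.errors[k] for k in keys],
        }
    )


# -- treemap ---------------------------------------------------------------


@dataclass(frozen=True)
class TreemapLayout:
    """Rectangles (id, x, y, w, h, shade) tiling ``canvas`` by area share."""

    rectangles: list[tuple[str, float, float, float, float, float]]
    canvas: tuple[float, float]


def _worst_aspect(row: list[float], side: float) -> float:
    s = sum(row)
    w = s / side  # thickness of the strip
    return max(max(r / w, w / r) for r in (a / w for a in row))


def _layout_row(row, x, y, w, h):
    """Place one strip of rectangles along the shorter side; return new free box."""
    s = sum(a for _, a in row)
    out = []
    if w >= h:  # vertical strip on the left
        strip = s / h
        cy = y
        for key, a in row:
            rh = a / strip
            out.append((key, x, cy, strip, rh))
            cy += rh
        return out, x + strip, y, w - strip, h
    strip = s / w
    cx = x
    for key, a in row:
        rw = a / strip
        out.append((key, cx, y, rw, strip))
        cx += rw
    return out, x, y + strip, w, h - strip


def treemap_layout(
    profile: ShapeProfile, canvas: tuple[float, float] = (100.0, 100.0)
) -> TreemapLayout:
    """Squarified treemap of a profile: area proportional to count.

    Zero-count sub-hierarchies are omitted (zero area).  The shade channel is
    ``count / max_count`` so darker rectangles hold more classes.
    """
    width, height = canvas
    if width <= 0 or height <= 0:
        raise ArgumentError("canvas dimensions must be positive")
    items = sorted(
        ((k, c) for k, c in profile.counts.items() if c > 0),
        key=lambda kv: (-kv[1], kv[0]),
    )
    if not items:
        raise ArgumentError("profile has no classes to lay out")
    total = sum(c for _, c in items)
    maxc = items[0][1]
    scale = width * height / total
    areas = [(k, c * scale) for k, c in items]

    rects: list[tuple[str, float, float, float, float]] = []
    x, y, w, h = 0.0, 0.0, width, height
    row: list[tuple[str, float]] = []
    i = 0
    while i < len(areas):
        side = min(w, h)
        candidate = row + [areas[i]]
        if not row or _worst_aspect(
            [a for _, a in candidate], side
        ) <= _worst_aspect([a for _, a in row], side):
            row = candidate
            i += 1
        else:
            placed, x, y, w, h = _layout_row(row, x, y, w, h)
            rects.extend(placed)
            row = []
    if row:
        placed, x, y, w, h = _layout_row(row, x, y, w, h)
        rects.extend(placed)

    shade = {k: c / maxc for k, c in items}
    return TreemapLayout(
        [(k, rx, ry, rw, rh, shade[k]) for k, rx, ry, rw, rh in rects],
        (width, height),
    )


def treemap_svg(layout: TreemapLayout, title: str = "") -> str:
    """Render a layout as a standalone SVG document (grey-scale by shade)."""
    w, h = layout.canvas
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" viewBox="0 0 {w} {h}" '
        f'width="{w}" height="{h}">',
    ]
    if title:
        parts.append(f"<title>{title}</title>")
    for key, x, y, rw, rh, shade in layout.rectangles:
        grey = int(round(230 - 180 * shade))
        parts.append(
            f'<rect x="{x:.4f}" y="{y:.4f}" width="{rw:.4f}" height="{rh:.4f}" '
            f'fill="rgb({grey},{grey},{grey})" stroke="white" stroke-width="0.5">'
            f"<title>{key}</title></rect>"
        )
        if rw > 6 and rh > 4:
            parts.append(
                f'<text x="{x + rw / 2:.4f}" y="{y + rh / 2:.4f}" '
                f'font-size="3" text-anchor="middle">{key}</text>'
            )
    parts.append("</svg>")
    return "\n".join(parts)
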