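"""Renderer-independent map geometry.

Converts an annotation plus a style into a circular (two concentric rings:
outer = forward strand, inner = reverse strand) or linear (two rows: upper
= forward, lower = reverse) arrangement of arrow glyphs with placed,
collision-resolved labels.

Conventions
-----------
* Canvas coordinates are logical pixels with the origin at the top-left and
  y growing downward (screen convention); the logical canvas is defined at
  100 dpi and scaled at render time.
* Circular angles are degrees clockwise from 12 o'clock; a position ``p``
  on a genome of length ``L`` maps to ``360 p / L``.
* Label rotations are degrees counter-clockwise on screen (the convention
  of every 2-D plotting backend); helpers here convert from map angles.
* Text is measured with a fixed per-character advance, never real font
  metrics, so layouts are bit-identical across platforms and font stacks.

Label policy: a feature name is drawn inside its arrow when it fits
(tangentially in circular maps); otherwise it is drawn beside the arrow at
90° (radially / vertically), and a bounded greedy sweep nudges clashing
external labels forward until their boxes no longer intersect.  Circular
layouts finish with an auto-fit that shrinks the rings until every label
box lies inside the canvas margin.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

from .errors import LinearTopology, UnfittableCanvas
from .model import Color, Feature, FeatureClass, GenomeAnnotation, Strand, Topology

#: logical pixels per inch of the abstract canvas
LOGICAL_DPI = 100

DEFAULT_PALETTE: Dict[FeatureClass, Color] = {
    FeatureClass.PCG: (77, 136, 86),
    FeatureClass.tRNA: (235, 134, 54),
    FeatureClass.rRNA: (104, 98, 190),
    FeatureClass.other: (160, 160, 160),
}


class Band(str, Enum):
    outer = "outer"    # circular, forward strand
    inner = "inner"    # circular, reverse strand
    upper = "upper"    # linear, forward strand
    lower = "lower"    # linear, reverse strand


class LabelMode(str, Enum):
    internal = "internal"
    external = "external"


@dataclass(frozen=True)
class Style:
    """All visual parameters of a map.

    Lengths are logical pixels (at 100 dpi) unless noted.  ``ring_radius``
    is the outer-ring centerline as a fraction of the half-canvas;
    ``char_advance`` is the fixed per-character text advance at
    ``font_size``; ``label_offsets`` holds manual per-feature anchor deltas
    (degrees in circular maps, pixels in linear maps) that exempt a label
    from the automatic clash sweep.
    """

    canvas_size: Tuple[float, float] = (800.0, 800.0)
    ring_radius: float = 0.72
    ring_thickness: float = 26.0
    ring_gap: float = 14.0
    font_size: float = 10.0
    char_advance: float = 6.0
    label_clearance: float = 4.0
    margin: float = 20.0
    palette: Dict[FeatureClass, Color] = field(
        default_factory=lambda: dict(DEFAULT_PALETTE)
    )
    arrowhead_fraction: float = 0.35
    label_offsets: Dict[str, float] = field(default_factory=dict)
    max_label_shift_steps: int = 24

    def __post_init__(self) -> None:
        w, h = self.canvas_size
        if w <= 0 or h <= 0:
            raise ValueError("canvas dimensions must be positive")
        if not 0 < self.ring_radius <= 1:
            raise ValueError("ring_radius must be in (0, 1]")
        if not 0 < self.arrowhead_fraction <= 0.5:
            raise ValueError("arrowhead_fraction must be in (0, 0.5]")
        for name in (
            "ring_thickness",
            "ring_gap",
            "font_size",
            "char_advance",
            "label_clearance",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.margin < 0:
            raise ValueError("margin must be non-negative")

    def color_for(self, feature: Feature) -> Color:
        """Resolve fill color: feature override > class palette > default."""
        if feature.color is not None:
            return feature.color
        return self.palette.get(
            feature.feature_class, DEFAULT_PALETTE[feature.feature_class]
        )


@dataclass(frozen=True)
class ArrowGlyph:
    """One drawn arrow.  Circular glyphs use angles/radius; linear glyphs
    use x extents and a row centerline y.  ``end_angle`` may exceed 360° for
    origin-spanning features (one unbroken glyph); in linear maps the same
    feature is split into two pieces sharing one label, with
    ``carries_label``/``carries_head`` marking the primary piece and the
    3'-end piece."""

    feature: Feature
    band: Band
    color: Color
    thickness: float
    # circular
    start_angle: Optional[float] = None
    end_angle: Optional[float] = None
    radius: Optional[float] = None
    # linear
    start_x: Optional[float] = None
    end_x: Optional[float] = None
    y: Optional[float] = None
    carries_label: bool = True
    carries_head: bool = True

    @property
    def is_circular(self) -> bool:
        return self.start_angle is not None

    @property
    def span_degrees(self) -> float:
        return self.end_angle - self.start_angle

    @property
    def mid_angle(self) -> float:
        return (self.start_angle + self.end_angle) / 2.0

    @property
    def width(self) -> float:
        return self.end_x - self.start_x


@dataclass(frozen=True)
class LabelPlacement:
    """A placed feature name: anchor point, screen rotation, alignment, and
    an axis-aligned bounding box used for collision tests."""

    feature_name: str
    text: str
    mode: LabelMode
    x: float
    y: float
    rotation: float           # degrees CCW on screen
    ha: str                   # left | center | right
    va: str                   # top | center | bottom
    bbox: Tuple[float, float, float, float]  # x0, y0, x1, y1
    color: Color = (0, 0, 0)
    shifted_steps: int = 0
    manual: bool = False


@dataclass(frozen=True)
class Layout:
    """Geometry of one map: glyphs plus labels on a logical canvas."""

    kind: Topology
    canvas_size: Tuple[float, float]
    genome_length: int
    glyphs: Tuple[ArrowGlyph, ...]
    labels: Tuple[LabelPlacement, ...]
    scale_applied: float = 1.0
    annotation: Optional[GenomeAnnotation] = field(
        default=None, repr=False, compare=False
    )

    def to_json(self) -> str:
        def glyph_dict(g: ArrowGlyph) -> dict:
            return {
                "name": g.feature.name,
                "band": g.band.value,
                "color": list(g.color),
                "thickness": g.thickness,
                "start_angle": g.start_angle,
                "end_angle": g.end_angle,
                "radius": g.radius,
                "start_x": g.start_x,
                "end_x": g.end_x,
                "y": g.y,
                "carries_label": g.carries_label,
                "carries_head": g.carries_head,
            }

        def label_dict(l: LabelPlacement) -> dict:
            return {
                "feature_name": l.feature_name,
                "text": l.text,
                "mode": l.mode.value,
                "x": l.x,
                "y": l.y,
                "rotation": l.rotation,
                "ha": l.ha,
                "va": l.va,
                "bbox": list(l.bbox),
                "shifted_steps": l.shifted_steps,
            }

        return json.dumps(
            {
                "kind": self.kind.value,
                "canvas_size": list(self.canvas_size),
                "genome_length": self.genome_length,
                "scale_applied": self.scale_applied,
                "glyphs": [glyph_dict(g) for g in self.glyphs],
                "labels": [label_dict(l) for l in self.labels],
            },
            sort_keys=True,
        )


# ---------------------------------------------------------------------------
# elementary geometry
# ---------------------------------------------------------------------------

def position_to_angle(pos: float, genome_length: int) -> float:
    """Map a base-pair position to degrees clockwise from 12 o'clock."""
    if not 0 <= pos <= genome_length:
        raise ValueError(f"position {pos} outside [0, {genome_length}]")
    return 360.0 * pos / genome_length


def angle_point(
    angle_deg: float, radius: float, center: Tuple[float, float]
) -> Tuple[float, float]:
    """Canvas point at a map angle (clockwise from 12 o'clock, y down)."""
    theta = math.radians(angle_deg)
    return (
        center[0] + radius * math.sin(theta),
        center[1] - radius * math.cos(theta),
    )


def estimate_text_extent(text: str, style: Style) -> Tuple[float, float]:
    """Deterministic text size: fixed per-character advance, 1.2 em height."""
    if not text:
        raise ValueError("cannot measure empty text")
    return (style.char_advance * len(text), 1.2 * style.font_size)


def boxes_intersect(
    a: Tuple[float, float, float, float], b: Tuple[float, float, float, float]
) -> bool:
    """Strict overlap of two axis-aligned boxes (shared edges do not count)."""
    return a[0] < b[2] and b[0] < a[2] and a[1] < b[3] and b[1] < a[3]


def _aabb(points: Sequence[Tuple[float, float]]) -> Tuple[float, float, float, float]:
    xs = [p[0] for p in points]
    ys = [p[1] for p in points]
    return (min(xs), min(ys), max(xs), max(ys))


def _norm_rotation(rot: float) -> float:
    rot = rot % 360.0
    if rot > 180.0:
        rot -= 360.0
    return rot


# ---------------------------------------------------------------------------
# glyph construction
# ---------------------------------------------------------------------------

def _circular_glyphs(
    annotation: GenomeAnnotation, style: Style, r_outer: float, r_inner: float
) -> Tuple[ArrowGlyph, ...]:
    L = annotation.genome_length
    glyphs = []
    for f in annotation.features:
        a0 = position_to_angle(f.start, L)
        span = 360.0 * f.length / L
        radius = r_outer if f.strand is Strand.forward else r_inner
        band = Band.outer if f.strand is Strand.forward else Band.inner
        glyphs.append(
            ArrowGlyph(
                feature=f,
                band=band,
                color=style.color_for(f),
                thickness=style.ring_thickness,
                start_angle=a0,
                end_angle=a0 + span,
                radius=radius,
            )
        )
    return tuple(glyphs)


def _linear_glyphs(
    annotation: GenomeAnnotation, style: Style
) -> Tuple[ArrowGlyph, ...]:
    W, H = style.canvas_size
    L = annotation.genome_length
    usable = W - 2 * style.margin

    def x_of(pos: float) -> float:
        return style.margin + usable * pos / L

    y_upper = H / 2.0 - (style.ring_gap / 2.0 + style.ring_thickness / 2.0)
    y_lower = H / 2.0 + (style.ring_gap / 2.0 + style.ring_thickness / 2.0)

    glyphs = []
    for f in annotation.features:
        forward = f.strand is Strand.forward
        y = y_upper if forward else y_lower
        band = Band.upper if forward else Band.lower
        color = style.color_for(f)
        common = dict(
            feature=f, band=band, color=color, thickness=style.ring_thickness, y=y
        )
        if f.wraps(L):
            # split into a right-end piece and a left-end piece sharing one label
            right = (x_of(f.start), x_of(L))
            left = (x_of(0), x_of(f.end - L))
            right_w = right[1] - right[0]
            left_w = left[1] - left[0]
            label_on_right = right_w >= left_w
            # the 3' end sits on the left piece for forward features,
            # on the right piece for reverse features
            glyphs.append(
                ArrowGlyph(
                    start_x=right[0],
                    end_x=right[1],
                    carries_label=label_on_right,
                    carries_head=not forward,
                    **common,
                )
            )
            glyphs.append(
                ArrowGlyph(
                    start_x=left[0],
                    end_x=left[1],
                    carries_label=not label_on_right,
                    carries_head=forward,
                    **common,
                )
            )
        else:
            glyphs.append(
                ArrowGlyph(start_x=x_of(f.start), end_x=x_of(f.end), **common)
            )
    return tuple(glyphs)


def glyph_polygon(glyph: ArrowGlyph, style: Style) -> List[Tuple[float, float]]:
    """Arrow outline as a closed polygon in canvas pixels.

    The arrowhead occupies ``arrowhead_fraction`` of the glyph span and
    points 5'→3': clockwise / rightward for forward-strand features,
    counter-clockwise / leftward for reverse."""
    half_t = glyph.thickness / 2.0
    forward = glyph.feature.strand is Strand.forward
    if glyph.is_circular:
        W, H = style.canvas_size
        center = (W / 2.0, H / 2.0)
        a0, a1 = glyph.start_angle, glyph.end_angle
        span = a1 - a0
        head = min(style.arrowhead_fraction * span, span) if glyph.carries_head else 0.0
        if forward:
            body0, body1, tip = a0, a1 - head, a1
        else:
            body0, body1, tip = a0 + head, a1, a0
        steps = max(2, int(abs(body1 - body0) / 3.0) + 1)
        arc = [body0 + (body1 - body0) * i / steps for i in range(steps + 1)]
        r_out, r_in = glyph.radius + half_t, glyph.radius - half_t
        pts = [angle_point(a, r_out, center) for a in arc]
        if head > 0 and forward:
            pts.append(angle_point(tip, glyph.radius, center))
        pts += [angle_point(a, r_in, center) for a in reversed(arc)]
        if head > 0 and not forward:
            pts.append(angle_point(tip, glyph.radius, center))
        return pts
    x0, x1, y = glyph.start_x, glyph.end_x, glyph.y
    width = x1 - x0
    head = min(style.arrowhead_fraction * width, width) if glyph.carries_head else 0.0
    if forward:
        bx0, bx1, tip = x0, x1 - head, x1
    else:
        bx0, bx1, tip = x0 + head, x1, x0
    pts = [(bx0, y - half_t), (bx1, y - half_t)]
    if head > 0 and forward:
        pts.append((tip, y))
    pts += [(bx1, y + half_t), (bx0, y + half_t)]
    if head > 0 and not forward:
        pts.append((tip, y))
    return pts


# ---------------------------------------------------------------------------
# label placement
# ---------------------------------------------------------------------------

def _tangential_placement(
    glyph: ArrowGlyph, style: Style, center: Tuple[float, float]
) -> LabelPlacement:
    text = glyph.feature.name
    w, h = estimate_text_extent(text, style)
    m = glyph.mid_angle % 360.0
    x, y = angle_point(m, glyph.radius, center)
    rot = -m
    if 90.0 < m < 270.0:  # keep text upright
        rot += 180.0
    theta = math.radians(m)
    u = (math.sin(theta), -math.cos(theta))      # radial, outward
    v = (math.cos(theta), math.sin(theta))       # tangential
    corners = [
        (x + sv * v[0] * w / 2 + su * u[0] * h / 2,
         y + sv * v[1] * w / 2 + su * u[1] * h / 2)
        for sv in (-1, 1)
        for su in (-1, 1)
    ]
    return LabelPlacement(
        feature_name=glyph.feature.name,
        text=text,
        mode=LabelMode.internal,
        x=x,
        y=y,
        rotation=_norm_rotation(rot),
        ha="center",
        va="center",
        bbox=_aabb(corners),
        color=_contrast_color(glyph.color),
    )


def _radial_placement(
    name: str,
    anchor_deg: float,
    base_radius: float,
    style: Style,
    center: Tuple[float, float],
    shifted_steps: int = 0,
    manual: bool = False,
) -> LabelPlacement:
    w, h = estimate_text_extent(name, style)
    m = anchor_deg % 360.0
    theta = math.radians(m)
    u = (math.sin(theta), -math.cos(theta))
    v = (math.cos(theta), math.sin(theta))
    x, y = angle_point(m, base_radius, center)
    corners = [
        (x + u[0] * t + sv * v[0] * h / 2, y + u[1] * t + sv * v[1] * h / 2)
        for t in (0.0, w)
        for sv in (-1, 1)
    ]
    if m <= 180.0:
        rot, ha = 90.0 - m, "left"
    else:
        rot, ha = 270.0 - m, "right"
    return LabelPlacement(
        feature_name=name,
        text=name,
        mode=LabelMode.external,
        x=x,
        y=y,
        rotation=_norm_rotation(rot),
        ha=ha,
        va="center",
        bbox=_aabb(corners),
        shifted_steps=shifted_steps,
        manual=manual,
    )


def _vertical_placement(
    name: str,
    anchor_x: float,
    glyph: ArrowGlyph,
    style: Style,
    shifted_steps: int = 0,
    manual: bool = False,
) -> LabelPlacement:
    w, h = estimate_text_extent(name, style)
    above = glyph.band is Band.upper
    if above:
        base_y = glyph.y - glyph.thickness / 2.0 - style.label_clearance
        bbox = (anchor_x - h / 2, base_y - w, anchor_x + h / 2, base_y)
        ha = "left"
    else:
        base_y = glyph.y + glyph.thickness / 2.0 + style.label_clearance
        bbox = (anchor_x - h / 2, base_y, anchor_x + h / 2, base_y + w)
        ha = "right"
    return LabelPlacement(
        feature_name=name,
        text=name,
        mode=LabelMode.external,
        x=anchor_x,
        y=base_y,
        rotation=90.0,
        ha=ha,
        va="center",
        bbox=bbox,
        shifted_steps=shifted_steps,
        manual=manual,
    )


def place_labels(
    glyphs: Sequence[ArrowGlyph], style: Style, genome_length: int
) -> Tuple[LabelPlacement, ...]:
    """Place one label per feature with deterministic clash limiting.

    Names that fit inside their arrow are drawn there; the rest sit beside
    the arrow at 90°.  External labels are processed in (anchor, name)
    order and nudged forward in label-height steps while their box
    intersects any already-accepted box, up to a bounded number of steps;
    labels with a manual anchor offset in ``style.label_offsets`` are moved
    by that offset and exempt from nudging.
    """
    if not glyphs:
        return ()
    if glyphs[0].is_circular:
        return _place_labels_circular(glyphs, style)
    return _place_labels_linear(glyphs, style)


def _place_labels_circular(
    glyphs: Sequence[ArrowGlyph], style: Style
) -> Tuple[LabelPlacement, ...]:
    W, H = style.canvas_size
    center = (W / 2.0, H / 2.0)
    r_ring_outer_edge = max(g.radius for g in glyphs) + style.ring_thickness / 2.0
    base_radius = r_ring_outer_edge + style.label_clearance

    accepted: List[LabelPlacement] = []
    external_queue: List[Tuple[float, str, ArrowGlyph]] = []

    for g in glyphs:
        text = g.feature.name
        w, h = estimate_text_extent(text, style)
        arc_len = math.radians(g.span_degrees) * g.radius
        candidate = None
        if w <= arc_len - style.label_clearance and h <= g.thickness:
            candidate = _tangential_placement(g, style, center)
            if any(boxes_intersect(candidate.bbox, a.bbox) for a in accepted):
                candidate = None  # demote overlapping internal label
        if candidate is not None:
            accepted.append(candidate)
        else:
            external_queue.append((g.mid_angle % 360.0, g.feature.name, g))

    results = list(accepted)
    external_queue.sort(key=lambda item: (item[0], item[1]))
    for anchor, name, g in external_queue:
        manual_delta = style.label_offsets.get(name)
        if manual_delta is not None:
            placed = _radial_placement(
                name, anchor + manual_delta, base_radius, style, center, manual=True
            )
            results.append(placed)
            continue
        _, h = estimate_text_extent(name, style)
        step_deg = math.degrees(h / base_radius)
        steps = 0
        placed = _radial_placement(name, anchor, base_radius, style, center)
        while steps < style.max_label_shift_steps and any(
            boxes_intersect(placed.bbox, a.bbox) for a in results
        ):
            steps += 1
            placed = _radial_placement(
                name, anchor + steps * step_deg, base_radius, style, center,
                shifted_steps=steps,
            )
        results.append(placed)
    return tuple(results)


def _place_labels_linear(
    glyphs: Sequence[ArrowGlyph], style: Style
) -> Tuple[LabelPlacement, ...]:
    accepted: List[LabelPlacement] = []
    external_queue: List[Tuple[float, str, ArrowGlyph]] = []

    for g in glyphs:
        if not g.carries_label:
            continue
        text = g.feature.name
        w, h = estimate_text_extent(text, style)
        mid_x = (g.start_x + g.end_x) / 2.0
        candidate = None
        if w <= g.width - style.label_clearance and h <= g.thickness:
            bbox = (mid_x - w / 2, g.y - h / 2, mid_x + w / 2, g.y + h / 2)
            candidate = LabelPlacement(
                feature_name=g.feature.name,
                text=text,
                mode=LabelMode.internal,
                x=mid_x,
                y=g.y,
                rotation=0.0,
                ha="center",
                va="center",
                bbox=bbox,
                color=_contrast_color(g.color),
            )
            if any(boxes_intersect(candidate.bbox, a.bbox) for a in accepted):
                candidate = None
        if candidate is not None:
            accepted.append(candidate)
        else:
            external_queue.append((mid_x, g.feature.name, g))

    results = list(accepted)
    external_queue.sort(key=lambda item: (item[0], item[1]))
    for anchor_x, name, g in external_queue:
        manual_delta = style.label_offsets.get(name)
        if manual_delta is not None:
            results.append(
                _vertical_placement(name, anchor_x + manual_delta, g, style, manual=True)
            )
            continue
        _, h = estimate_text_extent(name, style)
        steps = 0
        placed = _vertical_placement(name, anchor_x, g, style)
        while steps < style.max_label_shift_steps and any(
            boxes_intersect(placed.bbox, a.bbox) for a in results
        ):
            steps += 1
            placed = _vertical_placement(
                name, anchor_x + steps * h, g, style, shifted_steps=steps
            )
        results.append(placed)
    return tuple(results)


def _contrast_color(fill: Color) -> Color:
    # ITU-R 601 luma; dark fills get white text
    luma = 0.299 * fill[0] + 0.587 * fill[1] + 0.114 * fill[2]
    return (255, 255, 255) if luma < 128 else (0, 0, 0)


# ---------------------------------------------------------------------------
# layouts
# ---------------------------------------------------------------------------

def _build_circular(
    annotation: GenomeAnnotation, style: Style, scale: float
) -> Layout:
    W, H = style.canvas_size
    half = min(W, H) / 2.0
    r_outer = style.ring_radius * half * scale
    r_inner = r_outer - style.ring_thickness - style.ring_gap
    if r_inner - style.ring_thickness / 2.0 <= 0:
        raise UnfittableCanvas(
            f"inner ring collapses at scale {scale:.3f} "
            f"(outer centerline {r_outer:.1f} px)"
        )
    glyphs = _circular_glyphs(annotation, style, r_outer, r_inner)
    labels = place_labels(glyphs, style, annotation.genome_length)
    return Layout(
        kind=Topology.circular,
        canvas_size=style.canvas_size,
        genome_length=annotation.genome_length,
        glyphs=glyphs,
        labels=labels,
        scale_applied=scale,
        annotation=annotation,
    )


def layout_circular(annotation: GenomeAnnotation, style: Optional[Style] = None) -> Layout:
    """Circular map: forward features on the outer ring, reverse on the
    inner ring, wrapping features as one unbroken glyph; labels placed and
    the whole map auto-fitted so no label leaves the canvas."""
    style = style or Style()
    if annotation.topology is not Topology.circular:
        raise LinearTopology("annotation is linear; use layout_linear")
    return fit_canvas(_build_circular(annotation, style, 1.0), style)


def layout_linear(annotation: GenomeAnnotation, style: Optional[Style] = None) -> Layout:
    """Linear map: forward features on the upper row, reverse on the lower
    row; an origin-spanning feature is split into right- and left-end
    pieces sharing one label."""
    style = style or Style()
    glyphs = _linear_glyphs(annotation, style)
    labels = place_labels(glyphs, style, annotation.genome_length)
    return Layout(
        kind=Topology.linear,
        canvas_size=style.canvas_size,
        genome_length=annotation.genome_length,
        glyphs=glyphs,
        labels=labels,
        scale_applied=1.0,
        annotation=annotation,
    )


_MAX_FIT_PASSES = 6


def fit_canvas(layout: Layout, style: Style) -> Layout:
    """Shrink a circular layout until every label box (and the rings) sits
    inside the canvas minus the margin.

    Each pass measures the worst radial overshoot, rescales all radii by
    ``(half - margin - overshoot_depth) / outer_radius``, and re-places
    labels at the new radii; a handful of passes converge because the
    overshoot is bounded by the longest name.  Raises
    :class:`UnfittableCanvas` when the required scale would drop the outer
    ring below four ring thicknesses.
    """
    if layout.kind is not Topology.circular:
        return layout
    W, H = layout.canvas_size
    center = (W / 2.0, H / 2.0)
    half = min(W, H) / 2.0
    limit = half - style.margin
    base_outer = style.ring_radius * half

    current = layout
    for _ in range(_MAX_FIT_PASSES):
        extents = [
            max(
                math.hypot(x - center[0], y - center[1])
                for x in (l.bbox[0], l.bbox[2])
                for y in (l.bbox[1], l.bbox[3])
            )
            for l in current.labels
        ]
        ring_edge = (
            max((g.radius for g in current.glyphs), default=0.0)
            + style.ring_thickness / 2.0
        )
        extent = max(extents + [ring_edge], default=0.0)
        if extent <= limit + 1e-9:
            return current
        r_outer = style.ring_radius * half * current.scale_applied
        depth = extent - r_outer
        # half-pixel pad so second-order bbox effects cannot stall convergence
        scale = (limit - depth - 0.5) / base_outer
        if scale <= 0 or scale * base_outer < 4 * style.ring_thickness:
            raise UnfittableCanvas(
                f"labels need {extent:.0f} px of radius but only "
                f"{limit:.0f} px fit inside the margin"
            )
        if current.annotation is None:
            raise UnfittableCanvas("layout carries no annotation to re-fit")
        current = _build_circular(current.annotation, style, scale)
    raise UnfittableCanvas("auto-fit did not converge")
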