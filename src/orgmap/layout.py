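"""Resolution-independent map geometry.

Converts a classified, analyzed record into abstract geometry: feature arcs
or boxes, intron gaps, operon bars, tick rulers, GC ring, IR brackets, cut
ticks and label anchors.  Nothing here knows about pixels or fonts beyond
abstract map units; rendering backends consume the result.

Drawing conventions, fixed once: nucleotide 1 sits at 0 deg = 3 o'clock and
angles grow clockwise; plus-strand features are drawn inside the circle
(transcribed clockwise), minus-strand outside; on linear maps the same
convention becomes above/below the axis.  The inverted repeat IR_A is the
right repeat — the copy ending at the map origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .feature_model import ClassifiedFeature, MapConfig
from .model import GenomeRecord, OrgmapError
from .seq_analysis import CutSite, GcProfile, RepeatPair

__all__ = [
    "DrawElement",
    "Ring",
    "MapLayout",
    "Analyses",
    "position_to_angle",
    "layout_circular",
    "layout_linear",
    "place_labels",
    "build_layout",
]

CANVAS = 1000.0  # abstract map units, both dimensions of a circular canvas
LINEAR_HEIGHT = 360.0
CHAR_W = 7.0  # abstract label character advance
LABEL_H = 14.0
R_BASE = 330.0  # baseline circle radius
ARC_THICK = 36.0
R_INNER_LABEL = R_BASE - ARC_THICK - 10.0
R_OUTER_LABEL = R_BASE + ARC_THICK + 10.0
TIER_STEP = LABEL_H + 2.0


@dataclass
class DrawElement:
    kind: str  # feature_arc|feature_box|intron_gap|label|tick|operon_bar|dloop_arc|cut_tick|expression_box
    class_id: str = ""
    color: str = "#000000"
    start: float = 0.0  # degrees (circular) or x in map units (linear)
    extent: float = 0.0
    side: str = "inner"  # inner|outer (circular), above|below (linear)
    text: str = ""
    tier: int = 0
    leader: bool = False
    meta: dict = field(default_factory=dict)


@dataclass
class Ring:
    kind: str  # gc | scale | ir_bracket | cutsites
    data: dict = field(default_factory=dict)


@dataclass
class Analyses:
    """Optional analysis results feeding extra rings/ticks."""

    gc: Optional[GcProfile] = None
    ir: Optional[RepeatPair] = None
    cut_sites: Sequence[CutSite] = ()


@dataclass
class MapLayout:
    shape: str  # circular | linear
    elements: list[DrawElement]
    rings: list[Ring]
    title: str
    legend: list[tuple[str, str]]
    width: float
    height: float
    length_bp: int
    zoom: Optional[tuple[int, int]] = None
    stretch: float = 1.0


def position_to_angle(pos: float, length: int) -> float:
    """Angle in degrees of a 1-based position: 360*(pos-1)/length, measured
    clockwise from 3 o'clock; position 1 maps to 0 deg."""
    if not (1 <= pos <= length + 1):
        raise OrgmapError(f"position {pos} out of range [1, {length}]")
    return 360.0 * (pos - 1) / length


def _tick_interval(span_bp: int) -> int:
    """Largest {1,2,5}x10^k interval giving 8-20 ticks across the span."""
    candidates = []
    for k in range(0, 8):
        for m in (1, 2, 5):
            candidates.append(m * 10**k)
    for c in sorted(candidates, reverse=True):
        if span_bp // c + 1 >= 8:
            return c
    return 1


def _element_color(cf: ClassifiedFeature, config: MapConfig) -> str:
    name = cf.gene_id
    if name and name in config.gene_colors:
        return config.gene_colors[name]
    cls = config.class_by_id(cf.class_id)
    return cls.color if cls else "#808080"


def _feature_kind(cf: ClassifiedFeature, circular: bool) -> str:
    if cf.class_id == "dloop":
        return "dloop_arc" if circular else "feature_box"
    if cf.class_id == "operon" or cf.feature.key in ("prim_transcript", "operon"):
        return "operon_bar"
    return "feature_arc" if circular else "feature_box"


def _used_legend(
    classified: Sequence[ClassifiedFeature], config: MapConfig
) -> list[tuple[str, str]]:
    seen: list[str] = []
    for cf in classified:
        if not cf.suppressed and cf.class_id not in seen:
            seen.append(cf.class_id)
    legend = []
    for cls in config.classes:
        if cls.class_id in seen and cls.enabled:
            legend.append((cls.display_label, cls.color))
    return legend


# ---------------------------------------------------------------------------
# circular


def layout_circular(
    record: GenomeRecord,
    classified: Sequence[ClassifiedFeature],
    analyses: Analyses,
    config: MapConfig,
) -> MapLayout:
    """Geometry for a circular map.

    Origin-spanning features become one continuous arc across 0 deg (their
    stored extent then crosses 360).  With box-style introns, multi-part
    genes are drawn part-by-part with empty intron gaps in between; with
    asterisk style the gene is one arc and only the label carries the mark.
    """
    if config.zoom is not None:
        raise OrgmapError("zoom is available for linear maps only")
    L = record.length_bp
    elements: list[DrawElement] = []

    for cf in classified:
        if cf.suppressed:
            continue
        loc = cf.feature.location
        first, _last, span = loc.extent(L)
        side = "inner" if loc.strand == "+" else "outer"
        color = _element_color(cf, config)
        kind = _feature_kind(cf, circular=True)
        draw_parts: list[tuple[int, int, str]] = []  # (start, span_bp, kind)
        if (
            config.intron_style == "box"
            and cf.has_intron
            and cf.exon_parts
            and kind == "feature_arc"
        ):
            ordered = sorted(cf.exon_parts)
            for i, (s, e) in enumerate(ordered):
                draw_parts.append((s, e - s + 1, "feature_arc"))
                if i + 1 < len(ordered):
                    gap_s = e + 1
                    gap_span = ordered[i + 1][0] - gap_s
                    if gap_span > 0:
                        draw_parts.append((gap_s, gap_span, "intron_gap"))
        else:
            draw_parts.append((first, span, kind))
        for s, bp, k in draw_parts:
            elements.append(
                DrawElement(
                    kind=k,
                    class_id=cf.class_id,
                    color="#FFFFFF" if k == "intron_gap" else color,
                    start=position_to_angle(s, L),
                    extent=360.0 * bp / L,
                    side=side,
                    meta={"span_bp": bp, "gene": cf.gene_id or ""},
                )
            )
        if cf.display_name:
            anchor = position_to_angle(first, L) + 360.0 * span / L / 2.0
            elements.append(
                DrawElement(
                    kind="label",
                    class_id=cf.class_id,
                    color="#000000",
                    start=anchor % 360.0,
                    extent=len(cf.display_name) * CHAR_W,
                    side=side,
                    text=cf.display_name,
                )
            )

    rings: list[Ring] = [
        Ring("scale", {"interval": _tick_interval(L), "length_bp": L, "radius": R_BASE})
    ]
    if config.show_gc and analyses.gc is not None:
        rings.append(
            Ring(
                "gc",
                {
                    "profile": analyses.gc,
                    "reference": 0.5,  # reference circle at the 50% threshold
                    "r_inner": 120.0,
                    "r_outer": 200.0,
                },
            )
        )
    if analyses.ir is not None:
        ir = analyses.ir
        rings.append(
            Ring(
                "ir_bracket",
                {
                    "ir_a": (
                        position_to_angle(ir.ir_a[0], L),
                        360.0 * (ir.ir_a[1] - ir.ir_a[0] + 1) / L,
                    ),
                    "ir_b": (
                        position_to_angle(ir.ir_b[0], L),
                        360.0 * (ir.ir_b[1] - ir.ir_b[0] + 1) / L,
                    ),
                    "labels": ("IRA", "IRB"),
                    "radius": R_BASE + 2 * ARC_THICK + 30.0,
                },
            )
        )
    for site in analyses.cut_sites:
        elements.append(
            DrawElement(
                kind="cut_tick",
                class_id="cutsite",
                color="#333333",
                start=position_to_angle(site.position, L),
                extent=0.0,
                side="outer",
                text=site.enzyme,
            )
        )

    layout = MapLayout(
        shape="circular",
        elements=elements,
        rings=rings,
        title=f"{record.organism or record.accession}  {record.accession}  "
        f"{L:,} bp".strip(),
        legend=_used_legend(classified, config),
        width=CANVAS,
        height=CANVAS,
        length_bp=L,
    )
    return place_labels(layout)


# ---------------------------------------------------------------------------
# linear


def layout_linear(
    record: GenomeRecord,
    classified: Sequence[ClassifiedFeature],
    analyses: Analyses,
    config: MapConfig,
) -> MapLayout:
    """Geometry for a linear map, optionally zoomed to a window.

    x(pos) = stretch * (pos - window_start), with the stretch factor chosen
    so the window exactly fills the canvas width (stretch = width / window
    length) unless overridden.  Features are clipped to the window; clipped
    edges are flagged in element metadata.
    """
    L = record.length_bp
    zoom = config.zoom or (1, L)
    zs, ze = zoom
    if not (1 <= zs < ze <= L):
        raise OrgmapError(f"zoom window {zoom} invalid for length {L}")
    window = ze - zs + 1
    stretch = config.stretch_factor or CANVAS / window

    def x_of(pos: int) -> float:  # left edge of base `pos`
        return stretch * (pos - zs)

    elements: list[DrawElement] = []
    for cf in classified:
        if cf.suppressed:
            continue
        loc = cf.feature.location
        side = "above" if loc.strand == "+" else "below"
        color = _element_color(cf, config)
        kind = _feature_kind(cf, circular=False)
        boxes: list[tuple[int, int, str]] = []
        if config.intron_style == "box" and cf.has_intron and cf.exon_parts:
            ordered = sorted(cf.exon_parts)
            for i, (s, e) in enumerate(ordered):
                boxes.append((s, e, kind))
                if i + 1 < len(ordered) and ordered[i + 1][0] > e + 1:
                    boxes.append((e + 1, ordered[i + 1][0] - 1, "intron_gap"))
        elif loc.wraps_origin:
            boxes.extend((s, e, kind) for s, e in loc.parts)
        else:
            first, last, _ = loc.extent(L)
            boxes.append((first, last, kind))
        drawn_any = False
        for s, e, k in boxes:
            cs, ce = max(s, zs), min(e, ze)
            if cs > ce:
                continue
            drawn_any = True
            elements.append(
                DrawElement(
                    kind=k if k != "feature_arc" else "feature_box",
                    class_id=cf.class_id,
                    color="#FFFFFF" if k == "intron_gap" else color,
                    start=x_of(cs),
                    extent=stretch * (ce - cs + 1),
                    side=side,
                    meta={
                        "span_bp": ce - cs + 1,
                        "gene": cf.gene_id or "",
                        "clipped_left": cs > s,
                        "clipped_right": ce < e,
                    },
                )
            )
        if drawn_any and cf.display_name:
            first, last, _ = loc.extent(L)
            cs, ce = max(first, zs), min(last, ze)
            elements.append(
                DrawElement(
                    kind="label",
                    class_id=cf.class_id,
                    color="#000000",
                    start=(x_of(cs) + x_of(ce) + stretch) / 2.0,
                    extent=len(cf.display_name) * CHAR_W,
                    side=side,
                    text=cf.display_name,
                )
            )

    rings = [
        Ring(
            "scale",
            {
                "interval": _tick_interval(window),
                "length_bp": L,
                "window": (zs, ze),
                "stretch": stretch,
            },
        )
    ]
    for site in analyses.cut_sites:
        if zs <= site.position <= ze:
            elements.append(
                DrawElement(
                    kind="cut_tick",
                    class_id="cutsite",
                    color="#333333",
                    start=x_of(site.position),
                    extent=0.0,
                    side="above",
                    text=site.enzyme,
                )
            )

    layout = MapLayout(
        shape="linear",
        elements=elements,
        rings=rings,
        title=f"{record.organism or record.accession}  {record.accession}  "
        f"{L:,} bp".strip(),
        legend=_used_legend(classified, config),
        width=CANVAS,
        height=LINEAR_HEIGHT,
        length_bp=L,
        zoom=(zs, ze),
        stretch=stretch,
    )
    return place_labels(layout)


# ---------------------------------------------------------------------------
# labels


def _angular_width(label: DrawElement) -> float:
    radius = R_INNER_LABEL if label.side == "inner" else R_OUTER_LABEL
    import math

    return label.extent / (2 * math.pi * radius) * 360.0


def _intervals_overlap_circ(a0, a1, b0, b1) -> bool:
    # compare on the circle: shift everything near a0
    da = ((b0 - a0) % 360.0, (b1 - a0) % 360.0)
    span_a = (a1 - a0) % 360.0
    lo, hi = da
    if lo <= hi:
        return lo < span_a
    return True  # b wraps across a0


def place_labels(layout: MapLayout) -> MapLayout:
    """Deterministic greedy label placement in coordinate order.

    A label colliding with an already-placed one on the same side and tier
    is pushed outward (circular) or to the next stacking tier (linear) and
    gets a leader line; labels are never dropped.
    """
    labels = [e for e in layout.elements if e.kind == "label"]
    labels.sort(key=lambda e: (e.start, e.text))
    placed: dict[tuple[str, int], list[tuple[float, float]]] = {}
    for lab in labels:
        if layout.shape == "circular":
            w = _angular_width(lab)
            a0 = (lab.start - w / 2.0) % 360.0
            a1 = (a0 + w) % 360.0
            tier = 0
            while any(
                _intervals_overlap_circ(a0, a1, b0, b1)
                for b0, b1 in placed.get((lab.side, tier), ())
            ):
                tier += 1
            placed.setdefault((lab.side, tier), []).append((a0, a1))
        else:
            x0 = lab.start - lab.extent / 2.0
            x1 = lab.start + lab.extent / 2.0
            tier = 0
            while any(
                x0 < b1 and b0 < x1 for b0, b1 in placed.get((lab.side, tier), ())
            ):
                tier += 1
            placed.setdefault((lab.side, tier), []).append((x0, x1))
        lab.tier = tier
        lab.leader = tier > 0
    return layout


# ---------------------------------------------------------------------------
# one-call convenience


def build_layout(
    record: GenomeRecord,
    classified: Sequence[ClassifiedFeature],
    analyses: Analyses,
    config: MapConfig,
    shape: str = "auto",
) -> MapLayout:
    """Dispatch to circular or linear layout; ``auto`` follows the record
    topology from the LOCUS line."""
    if shape == "auto":
        shape = record.topology
    if shape == "circular":
        return layout_circular(record, classified, analyses, config)
    if shape == "linear":
        return layout_linear(record, classified, analyses, config)
    raise OrgmapError(f"unknown map shape {shape!r}")
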