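"""Serialize a :class:`~orgmap.layout.MapLayout` to image files.

SVG is produced by a purpose-built writer whose output is byte-deterministic
for a given layout: stable element order, floats fixed at 3 decimals, no
timestamps.  PDF/PS and the raster formats (PNG/TIFF/JPEG) are drawn from
the same layout object through matplotlib, so every format shows the same
geometry.
"""

from __future__ import annotations

import math
import zipfile
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .layout import (
    ARC_THICK,
    LABEL_H,
    R_BASE,
    R_INNER_LABEL,
    R_OUTER_LABEL,
    TIER_STEP,
    DrawElement,
    MapLayout,
)
from .model import OrgmapError

__all__ = ["RenderJob", "render_svg", "render_all", "bundle_zip"]

SUPPORTED_FORMATS = ("svg", "pdf", "ps", "png", "tiff", "jpeg")
UNITS_PER_INCH = 100.0  # abstract map units per inch when rasterizing
LEGEND_ROW = 22.0
AXIS_Y = 200.0  # linear map axis, in map units from the top


@dataclass
class RenderJob:
    layout: MapLayout
    formats: Sequence[str]
    dpi: int = 300
    output_basename: str = "map"

    def validate(self):
        if not self.formats:
            raise OrgmapError("no output formats requested")
        bad = [f for f in self.formats if f not in SUPPORTED_FORMATS]
        if bad:
            raise OrgmapError(
                f"unsupported format(s) {bad}; supported: {SUPPORTED_FORMATS}"
            )
        if self.dpi < 30:
            raise OrgmapError(f"dpi must be >= 30, got {self.dpi}")


def _f(v: float) -> str:
    s = f"{v:.3f}"
    return "-0.000".replace("-", "") if s == "-0.000" else s


def _pt(cx: float, cy: float, r: float, angle_deg: float) -> tuple[float, float]:
    # clockwise from 3 o'clock in SVG's y-down coordinate system
    rad = math.radians(angle_deg)
    return cx + r * math.cos(rad), cy + r * math.sin(rad)


def _arc_band_path(
    cx: float, cy: float, r_in: float, r_out: float, a0: float, extent: float
) -> str:
    extent = min(extent, 359.999)
    a1 = a0 + extent
    large = 1 if extent > 180.0 else 0
    x0o, y0o = _pt(cx, cy, r_out, a0)
    x1o, y1o = _pt(cx, cy, r_out, a1)
    x1i, y1i = _pt(cx, cy, r_in, a1)
    x0i, y0i = _pt(cx, cy, r_in, a0)
    return (
        f"M {_f(x0o)} {_f(y0o)} "
        f"A {_f(r_out)} {_f(r_out)} 0 {large} 1 {_f(x1o)} {_f(y1o)} "
        f"L {_f(x1i)} {_f(y1i)} "
        f"A {_f(r_in)} {_f(r_in)} 0 {large} 0 {_f(x0i)} {_f(y0i)} Z"
    )


def _band_radii(elem: DrawElement) -> tuple[float, float]:
    if elem.kind == "operon_bar":
        if elem.side == "inner":
            return R_BASE - ARC_THICK - 8.0, R_BASE - ARC_THICK - 2.0
        return R_BASE + ARC_THICK + 2.0, R_BASE + ARC_THICK + 8.0
    if elem.side == "inner":
        return R_BASE - ARC_THICK, R_BASE
    return R_BASE, R_BASE + ARC_THICK


def _svg_circular(layout: MapLayout, out: list[str]):
    cx = cy = layout.width / 2.0

    for ring in layout.rings:
        if ring.kind == "scale":
            out.append(
                f'<circle cx="{_f(cx)}" cy="{_f(cy)}" r="{_f(R_BASE)}" '
                f'fill="none" stroke="#000000" stroke-width="1.2"/>'
            )
            interval = ring.data["interval"]
            L = ring.data["length_bp"]
            pos = interval
            while pos <= L:
                a = 360.0 * (pos - 1) / L
                x0, y0 = _pt(cx, cy, R_BASE, a)
                x1, y1 = _pt(cx, cy, R_BASE - 6.0, a)
                out.append(
                    f'<line x1="{_f(x0)}" y1="{_f(y0)}" x2="{_f(x1)}" y2="{_f(y1)}" '
                    f'stroke="#000000" stroke-width="0.8"/>'
                )
                xt, yt = _pt(cx, cy, R_BASE - 16.0, a)
                label = f"{pos // 1000}kb" if interval >= 1000 else str(pos)
                out.append(
                    f'<text x="{_f(xt)}" y="{_f(yt)}" font-size="9" '
                    f'text-anchor="middle" fill="#444444">{label}</text>'
                )
                pos += interval
        elif ring.kind == "gc":
            r_in = ring.data["r_inner"]
            r_out = ring.data["r_outer"]
            profile = ring.data["profile"]
            L = layout.length_bp
            n = len(profile.values)
            for i, (_center, frac) in enumerate(profile.values):
                a0 = 360.0 * i / n
                ext = 360.0 / n
                r_top = r_in + (r_out - r_in) * frac
                out.append(
                    f'<path d="{_arc_band_path(cx, cy, r_in, r_top, a0, ext * 1.02)}" '
                    f'fill="#9AA5AC" stroke="none"/>'
                )
            r_ref = r_in + (r_out - r_in) * ring.data["reference"]
            out.append(
                f'<circle cx="{_f(cx)}" cy="{_f(cy)}" r="{_f(r_ref)}" fill="none" '
                f'stroke="#000000" stroke-width="0.8" stroke-dasharray="4 3" '
                f'class="gc-reference"/>'
            )
        elif ring.kind == "ir_bracket":
            r = ring.data["radius"]
            for key, lab in zip(("ir_a", "ir_b"), ring.data["labels"]):
                a0, ext = ring.data[key]
                out.append(
                    f'<path d="{_arc_band_path(cx, cy, r, r + 4.0, a0, ext)}" '
                    f'fill="#000000" stroke="none" class="ir-bracket"/>'
                )
                xm, ym = _pt(cx, cy, r + 16.0, (a0 + ext / 2.0) % 360.0)
                out.append(
                    f'<text x="{_f(xm)}" y="{_f(ym)}" font-size="11" '
                    f'text-anchor="middle">{lab}</text>'
                )

    for elem in layout.elements:
        if elem.kind in ("feature_arc", "dloop_arc", "intron_gap", "operon_bar", "expression_box"):
            if elem.kind == "expression_box":
                r_in, r_out = R_BASE + ARC_THICK + 12.0, R_BASE + ARC_THICK + 26.0
            else:
                r_in, r_out = _band_radii(elem)
            d = _arc_band_path(cx, cy, r_in, r_out, elem.start, elem.extent)
            stroke = ' stroke="#000000" stroke-width="0.5"'
            out.append(
                f'<path d="{d}" fill="{elem.color}"{stroke} class="{elem.kind}" '
                f'data-class="{elem.class_id}"/>'
            )
        elif elem.kind == "cut_tick":
            x0, y0 = _pt(cx, cy, R_BASE + ARC_THICK, elem.start)
            x1, y1 = _pt(cx, cy, R_BASE + ARC_THICK + 10.0, elem.start)
            out.append(
                f'<line x1="{_f(x0)}" y1="{_f(y0)}" x2="{_f(x1)}" y2="{_f(y1)}" '
                f'stroke="{elem.color}" stroke-width="1.0" class="cut_tick"/>'
            )
            xt, yt = _pt(cx, cy, R_BASE + ARC_THICK + 18.0, elem.start)
            out.append(
                f'<text x="{_f(xt)}" y="{_f(yt)}" font-size="8" '
                f'text-anchor="middle" fill="#333333">{elem.text}</text>'
            )
        elif elem.kind == "label":
            if elem.side == "inner":
                r = R_INNER_LABEL - elem.tier * TIER_STEP
                edge = R_BASE - ARC_THICK
            else:
                r = R_OUTER_LABEL + elem.tier * TIER_STEP
                edge = R_BASE + ARC_THICK
            x, y = _pt(cx, cy, r, elem.start)
            if elem.leader:
                xe, ye = _pt(cx, cy, edge, elem.start)
                out.append(
                    f'<line x1="{_f(xe)}" y1="{_f(ye)}" x2="{_f(x)}" y2="{_f(y)}" '
                    f'stroke="#888888" stroke-width="0.5"/>'
                )
            out.append(
                f'<text x="{_f(x)}" y="{_f(y)}" font-size="10" '
                f'font-style="italic" text-anchor="middle" '
                f'data-class="{elem.class_id}">{_esc(elem.text)}</text>'
            )


def _svg_linear(layout: MapLayout, out: list[str]):
    out.append(
        f'<line x1="0.000" y1="{_f(AXIS_Y)}" x2="{_f(layout.width)}" '
        f'y2="{_f(AXIS_Y)}" stroke="#000000" stroke-width="1.2"/>'
    )
    for ring in layout.rings:
        if ring.kind != "scale":
            continue
        interval = ring.data["interval"]
        zs, ze = ring.data["window"]
        stretch = ring.data["stretch"]
        pos = ((zs - 1) // interval + 1) * interval
        while pos <= ze:
            x = stretch * (pos - zs)
            out.append(
                f'<line x1="{_f(x)}" y1="{_f(AXIS_Y)}" x2="{_f(x)}" '
                f'y2="{_f(AXIS_Y + 6.0)}" stroke="#000000" stroke-width="0.8"/>'
            )
            label = f"{pos // 1000}kb" if interval >= 1000 else str(pos)
            out.append(
                f'<text x="{_f(x)}" y="{_f(AXIS_Y + 18.0)}" font-size="9" '
                f'text-anchor="middle" fill="#444444">{label}</text>'
            )
            pos += interval

    box_h = 26.0
    for elem in layout.elements:
        if elem.kind in ("feature_box", "intron_gap", "operon_bar", "expression_box"):
            h = 8.0 if elem.kind == "operon_bar" else box_h
            if elem.side == "above":
                y = AXIS_Y - 4.0 - h - (10.0 if elem.kind == "operon_bar" else 0.0)
            else:
                y = AXIS_Y + 4.0 + (10.0 + box_h if elem.kind == "operon_bar" else 0.0)
            marks = ""
            if elem.meta.get("clipped_left"):
                marks += " clipped-left"
            if elem.meta.get("clipped_right"):
                marks += " clipped-right"
            out.append(
                f'<rect x="{_f(elem.start)}" y="{_f(y)}" width="{_f(max(elem.extent, 0.5))}" '
                f'height="{_f(h)}" fill="{elem.color}" stroke="#000000" '
                f'stroke-width="0.5" class="{elem.kind}{marks}" '
                f'data-class="{elem.class_id}"/>'
            )
        elif elem.kind == "cut_tick":
            out.append(
                f'<line x1="{_f(elem.start)}" y1="{_f(AXIS_Y - 40.0)}" '
                f'x2="{_f(elem.start)}" y2="{_f(AXIS_Y)}" stroke="{elem.color}" '
                f'stroke-width="1.0" class="cut_tick"/>'
            )
            out.append(
                f'<text x="{_f(elem.start)}" y="{_f(AXIS_Y - 44.0)}" font-size="8" '
                f'text-anchor="middle" fill="#333333">{elem.text}</text>'
            )
        elif elem.kind == "label":
            if elem.side == "above":
                y = AXIS_Y - 40.0 - elem.tier * TIER_STEP
            else:
                y = AXIS_Y + 56.0 + elem.tier * TIER_STEP
            out.append(
                f'<text x="{_f(elem.start)}" y="{_f(y)}" font-size="10" '
                f'font-style="italic" text-anchor="middle" '
                f'data-class="{elem.class_id}">{_esc(elem.text)}</text>'
            )


def _esc(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
    )


def render_svg(layout: MapLayout) -> str:
    """Serialize a layout to SVG 1.1 text (byte-deterministic)."""
    legend_h = LEGEND_ROW * len(layout.legend) + (30.0 if layout.legend else 0.0)
    total_h = layout.height + legend_h
    out: list[str] = []
    out.append('<?xml version="1.0" encoding="UTF-8"?>')
    out.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_f(layout.width)}" height="{_f(total_h)}" '
        f'viewBox="0 0 {_f(layout.width)} {_f(total_h)}" '
        f'font-family="Helvetica, Arial, sans-serif">'
    )
    out.append(
        f'<rect x="0.000" y="0.000" width="{_f(layout.width)}" '
        f'height="{_f(total_h)}" fill="#FFFFFF"/>'
    )
    out.append(
        f'<text x="{_f(layout.width / 2.0)}" y="24.000" font-size="16" '
        f'text-anchor="middle" class="map-title">{_esc(layout.title)}</text>'
    )
    if layout.shape == "circular":
        _svg_circular(layout, out)
    else:
        _svg_linear(layout, out)

    y = layout.height + 20.0
    for label, color in layout.legend:
        out.append(
            f'<rect x="40.000" y="{_f(y)}" width="14.000" height="{_f(LABEL_H)}" '
            f'fill="{color}" stroke="#000000" stroke-width="0.5" class="legend-swatch"/>'
        )
        out.append(
            f'<text x="62.000" y="{_f(y + 11.0)}" font-size="11">{_esc(label)}</text>'
        )
        y += LEGEND_ROW
    out.append("</svg>")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# matplotlib backend for PDF/PS and raster formats


def _mpl_figure(layout: MapLayout):
    from matplotlib.figure import Figure
    from matplotlib.patches import Rectangle, Wedge

    legend_h = LEGEND_ROW * len(layout.legend) + (30.0 if layout.legend else 0.0)
    total_h = layout.height + legend_h
    fig = Figure(
        figsize=(layout.width / UNITS_PER_INCH, total_h / UNITS_PER_INCH)
    )
    ax = fig.add_axes([0, 0, 1, 1])
    ax.set_xlim(0, layout.width)
    ax.set_ylim(total_h, 0)  # y grows downward, matching the SVG writer
    ax.axis("off")
    ax.set_aspect("equal")

    def wedge(r_in, r_out, a0, ext, color, ecolor="#000000"):
        # y is inverted, so clockwise-from-3-o'clock angles can be used as-is
        ax.add_patch(
            Wedge(
                (layout.width / 2.0, layout.height / 2.0),
                r_out,
                a0,
                a0 + min(ext, 359.999),
                width=r_out - r_in,
                facecolor=color,
                edgecolor=ecolor,
                linewidth=0.4,
            )
        )

    ax.text(
        layout.width / 2.0, 24.0, layout.title, ha="center", va="center", fontsize=12
    )
    if layout.shape == "circular":
        cx = cy = layout.width / 2.0
        import matplotlib.patches as mpatches

        ax.add_patch(
            mpatches.Circle((cx, cy), R_BASE, fill=False, edgecolor="#000000", lw=1.0)
        )
        for ring in layout.rings:
            if ring.kind == "gc":
                r_in, r_out = ring.data["r_inner"], ring.data["r_outer"]
                profile = ring.data["profile"]
                n = len(profile.values)
                for i, (_c, frac) in enumerate(profile.values):
                    wedge(r_in, r_in + (r_out - r_in) * frac, 360.0 * i / n,
                          360.0 / n * 1.02, "#9AA5AC", ecolor="none")
                ax.add_patch(
                    mpatches.Circle(
                        (cx, cy),
                        r_in + (r_out - r_in) * ring.data["reference"],
                        fill=False, edgecolor="#000000", lw=0.6, linestyle="--",
                    )
                )
            elif ring.kind == "ir_bracket":
                r = ring.data["radius"]
                for key in ("ir_a", "ir_b"):
                    a0, ext = ring.data[key]
                    wedge(r, r + 4.0, a0, ext, "#000000", ecolor="none")
        for elem in layout.elements:
            if elem.kind in (
                "feature_arc", "dloop_arc", "intron_gap", "operon_bar", "expression_box",
            ):
                r_in, r_out = _band_radii(elem)
                wedge(r_in, r_out, elem.start, elem.extent, elem.color)
            elif elem.kind == "label":
                r = (
                    R_INNER_LABEL - elem.tier * TIER_STEP
                    if elem.side == "inner"
                    else R_OUTER_LABEL + elem.tier * TIER_STEP
                )
                x, y = _pt(cx, cy, r, elem.start)
                ax.text(x, y, elem.text, ha="center", va="center",
                        fontsize=7, fontstyle="italic")
    else:
        ax.plot([0, layout.width], [AXIS_Y, AXIS_Y], color="#000000", lw=1.0)
        for elem in layout.elements:
            if elem.kind in ("feature_box", "intron_gap", "operon_bar", "expression_box"):
                h = 8.0 if elem.kind == "operon_bar" else 26.0
                y = AXIS_Y - 4.0 - h if elem.side == "above" else AXIS_Y + 4.0
                ax.add_patch(
                    Rectangle(
                        (elem.start, y), max(elem.extent, 0.5), h,
                        facecolor=elem.color, edgecolor="#000000", lw=0.4,
                    )
                )
            elif elem.kind == "label":
                y = (
                    AXIS_Y - 40.0 - elem.tier * TIER_STEP
                    if elem.side == "above"
                    else AXIS_Y + 56.0 + elem.tier * TIER_STEP
                )
                ax.text(elem.start, y, elem.text, ha="center", va="center",
                        fontsize=7, fontstyle="italic")
    y = layout.height + 20.0
    for label, color in layout.legend:
        ax.add_patch(
            Rectangle((40.0, y), 14.0, LABEL_H, facecolor=color,
                      edgecolor="#000000", lw=0.4)
        )
        ax.text(62.0, y + 7.0, label, ha="left", va="center", fontsize=8)
        y += LEGEND_ROW
    return fig


def render_all(job: RenderJob) -> list[Path]:
    """Write one file per requested format next to ``output_basename``."""
    job.validate()
    base = Path(job.output_basename)
    base.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if "svg" in job.formats:
        path = Path(f"{base}.svg")  # accessions may contain dots
        path.write_text(render_svg(job.layout))
        written.append(path)
    other = [f for f in job.formats if f != "svg"]
    if other:
        fig = _mpl_figure(job.layout)
        for fmt in other:
            path = Path(f"{base}.{fmt}")
            save_kwargs: dict = {"format": fmt, "dpi": job.dpi}
            if fmt == "jpeg":
                save_kwargs["pil_kwargs"] = {"quality": 92}
            elif fmt == "tiff":
                save_kwargs["pil_kwargs"] = {"compression": "tiff_lzw"}
            elif fmt in ("pdf", "ps"):
                save_kwargs.pop("dpi")
            fig.savefig(path, **save_kwargs)
            written.append(path)
    return written


def bundle_zip(paths: Sequence[Path], zip_path: Path) -> Path:
    """Bundle output (and input) files into one zip archive."""
    zip_path = Path(zip_path)
    with zipfile.ZipFile(zip_path, "w", zipfile.ZIP_DEFLATED) as zf:
        for p in paths:
            zf.write(p, arcname=Path(p).name)
    return zip_path
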