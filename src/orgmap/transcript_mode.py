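"""Transcript mode: overlay per-gene expression values on a map.

Expression tables are two-column (gene, signed value, e.g. log2 fold
change) TSV/CSV files.  Each gene present in the dataset gets an overlay
box colored toward the up- or down-regulation hue; saturation scales
linearly with |value| up to ``max_abs`` (default: the dataset's largest
absolute value), zero maps to a neutral grey.  Geometry is never altered,
only colors and overlays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import IO, Optional, Union

from .feature_model import MapConfig
from .layout import DrawElement, MapLayout
from .model import OrgmapError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "read_expression_table",
    "expression_color",
    "apply_expression",
    "NEUTRAL_COLOR",
]

NEUTRAL_COLOR = "#C8C8C8"


@dataclass
class ExpressionDataset:
    values: dict[str, float] = field(default_factory=dict)
    dataset_label: str = ""

    @property
    def max_abs(self) -> float:
        return max((abs(v) for v in self.values.values()), default=1.0)


class ExpressionParseError(OrgmapError):
    pass


def read_expression_table(
    stream: Union[str, IO], dataset_label: str = ""
) -> ExpressionDataset:
    """Parse a two-column gene/value table (TSV or CSV, optional header)."""
    if isinstance(stream, str):
        with open(stream) as fh:
            lines = fh.read().splitlines()
        if not dataset_label:
            dataset_label = stream
    else:
        lines = stream.read().splitlines()

    values: dict[str, float] = {}
    n_rows = 0
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sep = "\t" if "\t" in line else ","
        cols = [c.strip() for c in line.split(sep)]
        if len(cols) < 2:
            raise ExpressionParseError(
                f"line {lineno}: expected 2 columns (gene, value), got {len(cols)}"
            )
        gene, raw = cols[0], cols[1]
        try:
            value = float(raw)
        except ValueError:
            if n_rows == 0:  # tolerated header row
                continue
            raise ExpressionParseError(
                f"line {lineno}: non-numeric value {raw!r} for gene {gene!r}"
            ) from None
        if not gene:
            raise ExpressionParseError(f"line {lineno}: empty gene name")
        if gene in values:
            logger.warning("duplicate gene %r in expression table; last wins", gene)
        values[gene] = value
        n_rows += 1
    if not values:
        raise ExpressionParseError("expression table contains no data rows")
    return ExpressionDataset(values=values, dataset_label=dataset_label)


def _hex_to_rgb(color: str) -> tuple[int, int, int]:
    return int(color[1:3], 16), int(color[3:5], 16), int(color[5:7], 16)


def expression_color(
    value: float, up_color: str, down_color: str, max_abs: float
) -> str:
    """Color for a signed expression value.

    Linear ramp from neutral grey at 0 toward the up/down hue, saturating
    at ``|value| >= max_abs``; symmetric in sign, monotone in magnitude.
    """
    if max_abs <= 0:
        raise OrgmapError("max_abs must be positive")
    if value == 0:
        return NEUTRAL_COLOR
    frac = min(abs(value) / max_abs, 1.0)
    target = _hex_to_rgb(up_color if value > 0 else down_color)
    neutral = _hex_to_rgb(NEUTRAL_COLOR)
    rgb = tuple(
        round(n + (t - n) * frac) for n, t in zip(neutral, target)
    )
    return "#{:02X}{:02X}{:02X}".format(*rgb)


def apply_expression(
    layout: MapLayout, dataset: ExpressionDataset, config: MapConfig,
    max_abs: Optional[float] = None,
) -> MapLayout:
    """Return a copy of the layout with per-gene expression overlay boxes.

    Every drawn gene element gains an ``expression_box`` at the same
    coordinates: colored by its dataset value, neutral grey when the gene
    is absent from the dataset.  Genes disabled in the configuration are
    already suppressed upstream and receive nothing.
    """
    if config.mode != "transcript":
        raise OrgmapError("apply_expression requires mode='transcript'")
    scale = max_abs if max_abs is not None else dataset.max_abs
    new_elements: list[DrawElement] = []
    seen_genes: set[str] = set()
    for elem in layout.elements:
        new_elements.append(elem)
        gene = elem.meta.get("gene") if elem.meta else None
        if (
            gene
            and elem.kind in ("feature_arc", "feature_box", "dloop_arc")
            and gene not in seen_genes
        ):
            seen_genes.add(gene)
            value = dataset.values.get(gene)
            color = (
                NEUTRAL_COLOR
                if value is None
                else expression_color(value, config.up_color, config.down_color, scale)
            )
            new_elements.append(
                replace(
                    elem,
                    kind="expression_box",
                    color=color,
                    meta={**elem.meta, "expression": value},
                )
            )
    return replace(layout, elements=new_elements)
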