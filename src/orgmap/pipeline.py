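"""Composition glue: record + config -> analyses -> layout.

Shared by the CLI and by library users who want a one-call map.
"""

from __future__ import annotations

from typing import Optional

from .feature_model import MapConfig, classify_features
from .layout import Analyses, MapLayout, build_layout
from .model import GenomeRecord
from .seq_analysis import find_inverted_repeats, gc_profile, scan_restriction_sites
from .transcript_mode import ExpressionDataset, apply_expression

__all__ = ["compute_analyses", "layout_record"]


def gc_window_for(length_bp: int) -> int:
    """GC window/step sized to ~400 bars around the circle, >= 50 bp."""
    return max(50, length_bp // 400)


def compute_analyses(
    record: GenomeRecord, config: MapConfig, shape: str = "auto"
) -> Analyses:
    """Run the sequence analyses a config asks for (GC ring, IR pair,
    restriction sites); analyses whose inputs are missing are skipped only
    when they were not explicitly requested."""
    shape = record.topology if shape == "auto" else shape
    gc = None
    if config.show_gc and shape == "circular" and record.sequence:
        w = gc_window_for(record.length_bp)
        gc = gc_profile(record, window_bp=w, step_bp=w)
    ir = None
    if config.ir_method != "none":
        ir = find_inverted_repeats(record, method=config.ir_method)
    cuts = ()
    if config.enzymes:
        cuts = scan_restriction_sites(record, list(config.enzymes))
    return Analyses(gc=gc, ir=ir, cut_sites=cuts)


def layout_record(
    record: GenomeRecord,
    config: MapConfig,
    shape: str = "auto",
    expression: Optional[ExpressionDataset] = None,
) -> MapLayout:
    """Classify, analyze and lay out one record; in transcript mode the
    expression overlay is applied on top."""
    classified = classify_features(record, config)
    analyses = compute_analyses(record, config, shape)
    layout = build_layout(record, classified, analyses, config, shape=shape)
    if config.mode == "transcript" and expression is not None:
        layout = apply_expression(layout, expression, config)
    return layout
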