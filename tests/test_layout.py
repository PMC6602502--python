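"""Geometry: angles, arcs, linear stretch/zoom/clipping, label placement."""

import itertools
import math
import random

import pytest

from orgmap import (
    Analyses,
    default_config,
    layout_circular,
    layout_linear,
    place_labels,
    position_to_angle,
    read_genbank_string,
)
from orgmap.feature_model import classify_features
from orgmap.fixtures import FixtureSpec, make_fixture
from orgmap.layout import CANVAS, DrawElement, MapLayout, _angular_width, \
    _intervals_overlap_circ
from orgmap.model import FeatureInstance, FeatureLocation, GenomeRecord, OrgmapError
from orgmap.pipeline import layout_record

ARC_KINDS = ("feature_arc", "dloop_arc", "intron_gap", "operon_bar")


def _record(L=10_000, topology="circular", features=()):
    return GenomeRecord(accession="T", organism="Test organism", length_bp=L,
                        topology=topology, features=list(features))


def _gene(start, end, name="psbA", strand="+", key="gene", wraps=False,
          parts=None):
    return FeatureInstance(
        key=key, gene_name=name,
        location=FeatureLocation(parts=tuple(parts or ((start, end),)),
                                 strand=strand, wraps_origin=wraps),
    )


class TestPositionToAngle:
    def test_first_base_at_three_oclock(self):
        assert position_to_angle(1, 16_569) == 0.0

    def test_half_way_is_180(self):
        assert position_to_angle(5_001, 10_000) == 180.0

    def test_quarter_turn(self):
        assert position_to_angle(2_501, 10_000) == 90.0

    def test_out_of_range(self):
        with pytest.raises(OrgmapError):
            position_to_angle(0, 100)


class TestCircularLayout:
    def _layout(self, record, config=None):
        config = config or default_config("plastid")
        classified = classify_features(record, config)
        return layout_circular(record, classified, Analyses(), config)

    def test_single_gene_quarter_arc_inner(self):
        rec = _record(features=[_gene(1, 2_500)])
        arcs = [e for e in self._layout(rec).elements if e.kind == "feature_arc"]
        assert len(arcs) == 1
        assert arcs[0].side == "inner"
        assert arcs[0].start == 0.0
        assert arcs[0].extent == pytest.approx(90.0, abs=1e-12)

    def test_minus_strand_goes_outside(self):
        rec = _record(features=[_gene(1, 2_500, strand="-")])
        arcs = [e for e in self._layout(rec).elements if e.kind == "feature_arc"]
        assert arcs[0].side == "outer"

    def test_arc_extent_matches_span(self, plastome):
        record, _, _ = plastome
        layout = layout_record(record, default_config("plastid"))
        for e in layout.elements:
            if e.kind in ARC_KINDS:
                want = 360.0 * e.meta["span_bp"] / record.length_bp
                assert e.extent == pytest.approx(want, rel=1e-9)

    def test_origin_spanning_feature_is_one_arc_crossing_zero(self):
        rec = _record(features=[_gene(9_500, 400, wraps=True,
                                      parts=((9_500, 10_000), (1, 400)))])
        arcs = [e for e in self._layout(rec).elements if e.kind == "feature_arc"]
        assert len(arcs) == 1
        assert arcs[0].start + arcs[0].extent > 360.0  # crosses the origin
        assert arcs[0].meta["span_bp"] == 901

    def test_rotation_rotates_all_arcs(self):
        rng = random.Random(6)
        L = 10_000
        delta = 1_000
        feats, rotated = [], []
        for _ in range(10):
            s = rng.randint(1, L - 500 - delta)  # never wraps after rotation
            e = s + rng.randint(50, 400)
            feats.append(_gene(s, e, name="psbA"))
            rotated.append(_gene(s + delta, e + delta, name="psbA"))
        lay_a = self._layout(_record(L, features=feats))
        lay_b = self._layout(_record(L, features=rotated))
        arcs_a = sorted(e.start for e in lay_a.elements if e.kind == "feature_arc")
        arcs_b = sorted(e.start for e in lay_b.elements if e.kind == "feature_arc")
        shift = 360.0 * delta / L
        expected = sorted((a + shift) % 360.0 for a in arcs_a)
        assert arcs_b == pytest.approx(expected, abs=1e-9)

    def test_intron_box_style_emits_gaps(self):
        config = default_config("plastid")
        config.intron_style = "box"
        rec = _record(features=[
            _gene(100, 900, name="clpP", key="CDS",
                  parts=((100, 400), (601, 900))),
        ])
        # CDS without a gene twin is structural; force-draw via key mapping
        config.key_classes["CDS"] = "clpP_matK"
        classified = classify_features(rec, config)
        layout = layout_circular(rec, classified, Analyses(), config)
        gaps = [e for e in layout.elements if e.kind == "intron_gap"]
        arcs = [e for e in layout.elements if e.kind == "feature_arc"]
        assert len(gaps) == 1 and len(arcs) == 2
        assert gaps[0].meta["span_bp"] == 200
        # asterisk style collapses to one arc, label marked instead
        config.intron_style = "asterisk"
        classified = classify_features(rec, config)
        layout = layout_circular(rec, classified, Analyses(), config)
        assert not [e for e in layout.elements if e.kind == "intron_gap"]
        labels = [e for e in layout.elements if e.kind == "label"]
        assert labels and labels[0].text.endswith("*")

    def test_operon_key_becomes_operon_bar(self):
        rec = _record(features=[_gene(100, 3_000, name=None, key="operon")])
        layout = self._layout(rec)
        assert [e.kind for e in layout.elements if e.kind != "label"] == ["operon_bar"]

    def test_suppressed_class_produces_no_elements(self, plastome):
        record, _, _ = plastome
        config = default_config("plastid")
        config.class_by_id("trna").enabled = False
        layout = layout_record(record, config)
        assert not [e for e in layout.elements if e.class_id == "trna"]

    def test_suppression_removes_only_that_class(self, plastome):
        record, _, _ = plastome
        base_cfg = default_config("plastid")
        layout_full = layout_record(record, base_cfg)
        config = default_config("plastid")
        config.class_by_id("trna").enabled = False
        layout_cut = layout_record(record, config)
        kept = [e for e in layout_full.elements if e.class_id != "trna"]
        assert [
            (e.kind, e.start, e.extent, e.class_id) for e in layout_cut.elements
        ] == [(e.kind, e.start, e.extent, e.class_id) for e in kept]

    def test_zoom_rejected_on_circular(self):
        config = default_config("plastid")
        config.zoom = (10, 500)
        rec = _record(features=[_gene(1, 100)])
        with pytest.raises(OrgmapError, match="linear"):
            self._layout(rec, config)

    def test_pure_function_determinism(self, plastome):
        record, _, _ = plastome
        a = layout_record(record, default_config("plastid"))
        b = layout_record(record, default_config("plastid"))
        assert a == b


class TestLinearLayout:
    def _layout(self, record, config=None):
        config = config or default_config("plastid")
        classified = classify_features(record, config)
        return layout_linear(record, classified, Analyses(), config)

    def test_stretch_fills_canvas(self):
        rec = _record(L=10_000, topology="linear",
                      features=[_gene(1, 1_000)])
        layout = self._layout(rec)
        assert layout.stretch == pytest.approx(CANVAS / 10_000)
        box = [e for e in layout.elements if e.kind == "feature_box"][0]
        assert box.start == pytest.approx(0.0)
        assert box.extent == pytest.approx(100.0)

    def test_zoom_window_mapping(self):
        config = default_config("plastid")
        config.zoom = (2_001, 3_000)
        rec = _record(L=10_000, topology="linear",
                      features=[_gene(2_501, 2_600)])
        layout = self._layout(rec, config)
        box = [e for e in layout.elements if e.kind == "feature_box"][0]
        assert box.start == pytest.approx(CANVAS * 0.5)
        assert box.start + box.extent == pytest.approx(CANVAS * 0.6)

    def test_max_x_equals_canvas(self):
        rng = random.Random(7)
        for _ in range(30):
            L = rng.randint(2_000, 50_000)
            rec = _record(L=L, topology="linear",
                          features=[_gene(L - 100, L)])
            layout = self._layout(rec)
            box = [e for e in layout.elements if e.kind == "feature_box"][0]
            assert box.start + box.extent == pytest.approx(CANVAS, abs=1e-6)

    def test_zoomed_equals_clipped_full_layout(self):
        rng = random.Random(8)
        L = 20_000
        feats = []
        for i in range(15):
            s = rng.randint(1, L - 600)
            feats.append(_gene(s, s + rng.randint(100, 500), name="psbA",
                               strand=rng.choice("+-")))
        rec = _record(L=L, topology="linear", features=feats)
        full = self._layout(rec)
        config = default_config("plastid")
        zs, ze = 5_001, 10_000
        config.zoom = (zs, ze)
        zoomed = self._layout(rec, config)
        # oracle: intersect full-layout boxes with the window, re-translate
        full_stretch = full.stretch
        zoom_stretch = zoomed.stretch
        expected = []
        for e in full.elements:
            if e.kind != "feature_box":
                continue
            b_start = e.start / full_stretch + 1  # back to bp
            b_end = b_start - 1 + e.meta["span_bp"]
            cs, ce = max(b_start, zs), min(b_end, ze)
            if cs > ce:
                continue
            expected.append((round(zoom_stretch * (cs - zs), 6),
                             round(zoom_stretch * (ce - cs + 1), 6)))
        got = [(round(e.start, 6), round(e.extent, 6))
               for e in zoomed.elements if e.kind == "feature_box"]
        assert sorted(got) == sorted(expected)

    def test_clipped_edges_flagged(self):
        config = default_config("plastid")
        config.zoom = (500, 1_500)
        rec = _record(L=10_000, topology="linear",
                      features=[_gene(100, 800)])
        layout = self._layout(rec, config)
        box = [e for e in layout.elements if e.kind == "feature_box"][0]
        assert box.meta["clipped_left"] and not box.meta["clipped_right"]

    def test_invalid_zoom_rejected(self):
        config = default_config("plastid")
        config.zoom = (5_000, 4_000)
        rec = _record(L=10_000, topology="linear", features=[])
        with pytest.raises(OrgmapError, match="zoom"):
            self._layout(rec, config)

    def test_strands_mirror_above_below(self):
        rec = _record(L=10_000, topology="linear", features=[
            _gene(100, 500, strand="+"), _gene(600, 900, name="rbcL", strand="-"),
        ])
        boxes = {e.meta["gene"]: e.side for e in self._layout(rec).elements
                 if e.kind == "feature_box"}
        assert boxes == {"psbA": "above", "rbcL": "below"}


class TestPlaceLabels:
    def _label(self, at, text="gene1", side="inner"):
        return DrawElement(kind="label", start=at, extent=len(text) * 7.0,
                           side=side, text=text)

    def _empty_layout(self, labels, shape="circular"):
        return MapLayout(shape=shape, elements=labels, rings=[], title="",
                         legend=[], width=1000, height=1000, length_bp=10_000)

    def test_disjoint_anchors_stay_on_tier_zero(self):
        layout = place_labels(self._empty_layout(
            [self._label(0.0), self._label(180.0)]))
        assert all(e.tier == 0 and not e.leader for e in layout.elements)

    def test_identical_anchors_forced_to_next_tier(self):
        layout = place_labels(self._empty_layout(
            [self._label(90.0), self._label(90.0)]))
        tiers = sorted(e.tier for e in layout.elements)
        assert tiers == [0, 1]
        assert [e.leader for e in layout.elements if e.tier == 1] == [True]

    @pytest.mark.parametrize("shape", ["circular", "linear"])
    def test_no_pairwise_overlap_after_pass(self, shape):
        rng = random.Random(9)
        if shape == "circular":
            labels = [self._label(rng.uniform(0, 360),
                                  side=rng.choice(["inner", "outer"]))
                      for _ in range(50)]
        else:
            labels = [DrawElement(kind="label", start=rng.uniform(0, 1000),
                                  extent=49.0, text="gene1",
                                  side=rng.choice(["above", "below"]))
                      for _ in range(50)]
        layout = place_labels(self._empty_layout(labels, shape))
        # oracle: pairwise bounding-interval intersection on each side+tier
        for a, b in itertools.combinations(layout.elements, 2):
            if (a.side, a.tier) != (b.side, b.tier):
                continue
            if shape == "circular":
                wa, wb = _angular_width(a), _angular_width(b)
                a0, a1 = (a.start - wa / 2) % 360, (a.start + wa / 2) % 360
                b0, b1 = (b.start - wb / 2) % 360, (b.start + wb / 2) % 360
                assert not _intervals_overlap_circ(a0, a1, b0, b1)
            else:
                assert (a.start + a.extent / 2 <= b.start - b.extent / 2
                        or b.start + b.extent / 2 <= a.start - a.extent / 2)

    def test_labels_never_dropped(self, plastome):
        record, _, _ = plastome
        layout = layout_record(record, default_config("plastid"))
        names = [e.text for e in layout.elements if e.kind == "label"]
        drawn = {e.meta["gene"] for e in layout.elements
                 if e.kind in ARC_KINDS and e.meta.get("gene")}
        assert {n.rstrip("*") for n in names} >= drawn
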