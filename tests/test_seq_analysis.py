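"""Scanners vs brute-force oracles; IR detection on planted repeats."""

import random

import pytest

from orgmap import (
    circular_distance,
    find_inverted_repeats,
    gc_profile,
    read_genbank_string,
    reverse_complement,
    scan_restriction_sites,
)
from orgmap.fixtures import (
    FixtureSpec,
    make_fixture,
    naive_cut_sites,
    naive_gc_windows,
)
from orgmap.model import GenomeRecord, OrgmapError, SequenceRequiredError
from orgmap.seq_analysis import load_enzyme_table


def _rec(seq, topology="linear", features=()):
    return GenomeRecord(
        accession="T1", organism="", length_bp=len(seq), sequence=seq,
        topology=topology, features=list(features),
    )


class TestCircularDistance:
    def test_same_position(self):
        assert circular_distance(1, 1, 10_000, "circular") == 0

    def test_wrap_around_is_shorter(self):
        assert circular_distance(9_990, 10, 10_000, "circular") == 20

    def test_linear_never_wraps(self):
        assert circular_distance(9_990, 10, 10_000, "linear") == 9_980

    def test_against_stepwise_walk(self):
        rng = random.Random(0)
        for _ in range(50):
            L = rng.randint(10, 500)
            a, b = rng.randint(1, L), rng.randint(1, L)
            # oracle: walk both directions one base at a time
            fwd = (b - a) % L
            bwd = (a - b) % L
            assert circular_distance(a, b, L, "circular") == min(fwd, bwd)
            assert circular_distance(a, b, L, "linear") == abs(b - a)

    def test_out_of_range_rejected(self):
        with pytest.raises(OrgmapError):
            circular_distance(0, 5, 10, "circular")


class TestGcProfile:
    def test_all_gc_is_one(self):
        prof = gc_profile(_rec("GGCC" * 300), 100, 100)
        assert all(v == 1.0 for _, v in prof.values)

    def test_all_at_is_zero(self):
        prof = gc_profile(_rec("ATAT" * 300), 100, 100)
        assert all(v == 0.0 for _, v in prof.values)

    def test_circular_window_count(self):
        prof = gc_profile(_rec("ACGT" * 300, topology="circular"), 100, 100)
        assert len(prof.values) == 12  # ceil(1200/100)

    def test_matches_naive_counting(self):
        rng = random.Random(1)
        for topology in ("circular", "linear"):
            seq = "".join(rng.choices("ACGTNSWR", weights=[8, 8, 8, 8, 1, 1, 1, 1],
                                      k=3_000))
            got = [v for _, v in gc_profile(_rec(seq, topology), 100, 100).values]
            want = naive_gc_windows(seq, 100, 100, topology)
            assert got == pytest.approx(want, abs=1e-12)
            assert len(got) == len(want)

    def test_rotation_invariance_up_to_relabeling(self):
        rng = random.Random(2)
        seq = "".join(rng.choices("ACGT", k=1_200))
        shift = 300  # multiple of the window
        rotated = seq[shift:] + seq[:shift]
        a = [v for _, v in gc_profile(_rec(seq, "circular"), 100, 100).values]
        b = [v for _, v in gc_profile(_rec(rotated, "circular"), 100, 100).values]
        assert b == a[3:] + a[:3]

    def test_requires_sequence(self):
        rec = GenomeRecord(accession="x", organism="", length_bp=100)
        with pytest.raises(SequenceRequiredError):
            gc_profile(rec, 10, 10)


class TestRestrictionScan:
    def test_ecori_simple(self):
        sites = scan_restriction_sites(_rec("GGAATTCC"), ["EcoRI"])
        assert [(s.position, s.strand) for s in sites] == [(2, "+")]

    def test_origin_spanning_site_on_circular(self):
        # GAAT at 9..12 wraps onto TC at 1..2
        sites = scan_restriction_sites(_rec("TCGGGGGGGAAT", "circular"), ["EcoRI"])
        assert [(s.position, s.strand) for s in sites] == [(9, "+")]

    def test_site_not_found_across_ends_when_linear(self):
        assert scan_restriction_sites(_rec("TCGGGGGGGAAT", "linear"), ["EcoRI"]) == []

    def test_unknown_enzyme_lists_valid_names(self):
        with pytest.raises(OrgmapError, match="EcoRI"):
            scan_restriction_sites(_rec("ACGT" * 10), ["NotAnEnzyme"])

    def test_degenerate_pattern_strict_genome_side(self):
        # DdeI site CTNAG: N on the pattern side matches any base, but an
        # ambiguity code in the genome must never match.
        assert [s.position for s in
                scan_restriction_sites(_rec("ACTGAGA"), ["DdeI"])] == [2]
        assert scan_restriction_sites(_rec("ACTNAGA"), ["DdeI"]) == []

    def test_matches_naive_oracle(self):
        rng = random.Random(3)
        table = load_enzyme_table()
        for trial in range(25):
            L = rng.randint(2_000, 5_000)
            seq = "".join(rng.choices("ACGTN", weights=[10] * 4 + [1], k=L))
            topology = rng.choice(["circular", "linear"])
            enzymes = rng.sample(sorted(table), 3)
            got = sorted(
                (s.enzyme, s.position, s.strand)
                for s in scan_restriction_sites(_rec(seq, topology), enzymes)
            )
            want = sorted(
                (e, p, strand)
                for e in enzymes
                for p, strand in naive_cut_sites(seq, table[e][0], topology)
            )
            assert got == want, (trial, topology, enzymes)

    def test_reverse_complement_mirror(self):
        rng = random.Random(4)
        seq = "".join(rng.choices("ACGT", k=2_000))
        table = load_enzyme_table()
        swap = {"+": "-", "-": "+"}
        # FokI/BsaI are non-palindromic, so strands must actually swap
        for enzyme in ("BamHI", "DdeI", "FokI", "BsaI"):
            site, _ = table[enzyme]
            m = len(site)
            palindromic = reverse_complement(site) == site
            fwd = scan_restriction_sites(_rec(seq), [enzyme])
            rev = scan_restriction_sites(_rec(reverse_complement(seq)), [enzyme])
            mirrored = sorted(
                (len(seq) - s.position - m + 2,
                 "+" if palindromic else swap[s.strand])
                for s in fwd
            )
            assert sorted((s.position, s.strand) for s in rev) == mirrored
            if enzyme in ("FokI", "BsaI"):
                assert any(s.strand == "-" for s in fwd + rev)


class TestInvertedRepeats:
    def test_planted_ir_recovered_exactly(self):
        text, truth = make_fixture(
            FixtureSpec(kind="plastome_like", length_bp=40_000, ir_len=4_000,
                        n_genes=10, seed=21)
        )
        record = read_genbank_string(text)[0]
        pair = find_inverted_repeats(record, "self_comparison",
                                     min_len=1_000, max_mismatch_frac=0.0)
        assert pair is not None
        assert pair.ir_a == truth.ir_a
        assert pair.ir_b == truth.ir_b
        assert pair.method == "self_comparison"

    def test_repeat_sequences_are_reverse_complements(self):
        text, _ = make_fixture(
            FixtureSpec(kind="plastome_like", length_bp=30_000, ir_len=3_000,
                        n_genes=5, seed=22)
        )
        record = read_genbank_string(text)[0]
        pair = find_inverted_repeats(record, "self_comparison",
                                     min_len=1_000, max_mismatch_frac=0.0)
        seq = record.sequence
        a = seq[pair.ir_a[0] - 1 : pair.ir_a[1]]
        b = seq[pair.ir_b[0] - 1 : pair.ir_b[1]]
        assert a == reverse_complement(b)

    def test_ir_a_is_the_repeat_ending_at_the_origin(self):
        text, truth = make_fixture(
            FixtureSpec(kind="plastome_like", length_bp=30_000, ir_len=3_000,
                        n_genes=5, seed=23)
        )
        record = read_genbank_string(text)[0]
        pair = find_inverted_repeats(record, "self_comparison",
                                     min_len=1_000, max_mismatch_frac=0.0)
        assert pair.ir_a[1] == record.length_bp
        assert pair.ir_a[1] > pair.ir_b[1]

    def test_no_repeat_returns_none(self):
        rng = random.Random(5)
        seq = "".join(rng.choices("ACGT", k=8_000))
        assert find_inverted_repeats(_rec(seq, "circular"), "self_comparison",
                                     min_len=1_000) is None

    def test_annotation_method_passes_through_coordinates(self):
        text, truth = make_fixture(
            FixtureSpec(kind="plastome_like", length_bp=30_000, ir_len=3_000,
                        n_genes=5, seed=24)
        )
        record = read_genbank_string(text)[0]
        pair = find_inverted_repeats(record, "annotation")
        assert pair.method == "annotation"
        assert (pair.ir_a, pair.ir_b) == (truth.ir_a, truth.ir_b)

    def test_method_none_disables(self, plastome):
        assert find_inverted_repeats(plastome[0], "none") is None

    def test_self_comparison_requires_sequence(self):
        rec = GenomeRecord(accession="x", organism="", length_bp=30_000)
        with pytest.raises(SequenceRequiredError):
            find_inverted_repeats(rec, "self_comparison")

    def test_noisy_ir_recovered_within_budget(self):
        text, truth = make_fixture(
            FixtureSpec(kind="plastome_like", length_bp=30_000, ir_len=3_000,
                        n_genes=5, seed=25, ir_mismatches=30)
        )
        record = read_genbank_string(text)[0]
        pair = find_inverted_repeats(record, "self_comparison",
                                     min_len=1_000, max_mismatch_frac=0.01)
        assert pair is not None
        for got, want in ((pair.ir_a, truth.ir_a), (pair.ir_b, truth.ir_b)):
            assert abs(got[0] - want[0]) <= 25
            assert abs(got[1] - want[1]) <= 25
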