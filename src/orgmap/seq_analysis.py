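"""Sequence-level analyses behind the map rings.

Implements circular coordinate arithmetic, sliding-window GC content,
inverted-repeat (IR) detection — either read from annotation or found de
novo by seed-and-extend self-comparison — and degenerate restriction-site
scanning against a shipped enzyme table.

IUPAC handling is strict and documented: on the genome side, ambiguity
codes never satisfy a restriction pattern; in GC windows, S counts as G/C
and W as A/T while all other ambiguity codes are excluded from numerator
and denominator alike.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import GenomeRecord, OrgmapError

__all__ = [
    "RepeatPair",
    "GcProfile",
    "CutSite",
    "circular_distance",
    "gc_profile",
    "find_inverted_repeats",
    "scan_restriction_sites",
    "load_enzyme_table",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans(
    "ACGTUMRWSYKVHDBNacgtumrwsykvhdbn",
    "TGCAAKYWSRMBDHVNtgcaakywsrmbdhvn",
)

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "M": "AC", "R": "AG", "W": "AT", "S": "CG", "Y": "CT", "K": "GT",
    "V": "ACG", "H": "ACT", "D": "AGT", "B": "CGT", "N": "ACGT",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# circular arithmetic


def circular_distance(a: int, b: int, length: int, topology: str) -> int:
    """Shortest distance in bp between positions ``a`` and ``b``.

    On a circular molecule the shorter way around is taken; on a linear one
    it is plain ``|b - a|``.
    """
    if not (1 <= a <= length and 1 <= b <= length):
        raise OrgmapError(
            f"positions ({a}, {b}) out of range for length {length}"
        )
    d = abs(b - a)
    if topology == "circular":
        return min(d, length - d)
    return d


# ---------------------------------------------------------------------------
# GC profile


@dataclass(frozen=True)
class GcProfile:
    window_bp: int
    step_bp: int
    values: tuple[tuple[float, float], ...]  # (window center position, gc fraction)


def gc_profile(record: GenomeRecord, window_bp: int = 100, step_bp: int = 100) -> GcProfile:
    """Sliding-window GC fraction; windows wrap the origin on circular records.

    gc = (#G + #C + #S) / (#A + #C + #G + #T + #S + #W) per window; other
    IUPAC codes are ignored on both sides of the ratio.  A window with no
    countable base reports 0.0.
    """
    seq = record.require_sequence("gc_profile").upper()
    L = len(seq)
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    is_gc = np.isin(arr, [b"G", b"C", b"S"]).astype(np.int64)
    is_counted = np.isin(arr, [b"A", b"C", b"G", b"T", b"S", b"W"]).astype(np.int64)

    circular = record.topology == "circular"
    if circular:
        n_windows = -(-L // step_bp)  # ceil
        is_gc = np.concatenate([is_gc, is_gc[: window_bp]])
        is_counted = np.concatenate([is_counted, is_counted[: window_bp]])
    else:
        n_windows = max(1, (L - window_bp) // step_bp + 1) if L >= window_bp else 1

    cum_gc = np.concatenate([[0], np.cumsum(is_gc)])
    cum_ct = np.concatenate([[0], np.cumsum(is_counted)])
    values = []
    for i in range(n_windows):
        start = i * step_bp  # 0-based window start
        end = min(start + window_bp, len(arr) if not circular else start + window_bp)
        gc = int(cum_gc[end] - cum_gc[start])
        ct = int(cum_ct[end] - cum_ct[start])
        frac = gc / ct if ct else 0.0
        center = (start + (end - start - 1) / 2.0) % L + 1.0
        values.append((center, frac))
    return GcProfile(window_bp=window_bp, step_bp=step_bp, values=tuple(values))


# ---------------------------------------------------------------------------
# inverted repeats


@dataclass(frozen=True)
class RepeatPair:
    """A pair of inverted repeats.

    ``ir_a`` is the repeat drawn on the right of a circular map: the copy
    immediately upstream (counter-clockwise) of nucleotide 1, i.e. the one
    whose end is closest to the sequence end.
    """

    ir_a: tuple[int, int]
    ir_b: tuple[int, int]
    length_bp: int
    method: str  # "annotation" | "self_comparison"


_IR_NOTE_RE = re.compile(r"inverted\s*repeat|IR[\s_\-]?[AB]\b|\bIR[ab]\b", re.IGNORECASE)


def _annotation_ir(record: GenomeRecord) -> Optional[RepeatPair]:
    hits = []
    for feat in record.features:
        text = " ".join(
            feat.raw_qualifiers.get(q, "") for q in ("note", "rpt_type", "standard_name")
        )
        if feat.key == "repeat_region" and (
            _IR_NOTE_RE.search(text) or feat.raw_qualifiers.get("rpt_type") == "inverted"
        ):
            lo, hi, _ = feat.location.extent(record.length_bp)
            hits.append((lo, hi))
        elif feat.key != "repeat_region" and _IR_NOTE_RE.search(text):
            lo, hi, _ = feat.location.extent(record.length_bp)
            hits.append((lo, hi))
    if len(hits) < 2:
        return None
    hits.sort(key=lambda se: se[1] - se[0], reverse=True)
    pair = sorted(hits[:2])
    return _orient_pair(pair[0], pair[1], record.length_bp, "annotation")


def _orient_pair(
    seg1: tuple[int, int], seg2: tuple[int, int], length: int, method: str
) -> RepeatPair:
    # IR_A ends closer (going clockwise) to position 1 than IR_B does.
    gap1 = (length - seg1[1]) % length
    gap2 = (length - seg2[1]) % length
    ir_a, ir_b = (seg1, seg2) if gap1 <= gap2 else (seg2, seg1)
    rep_len = max(seg1[1] - seg1[0] + 1, seg2[1] - seg2[0] + 1)
    return RepeatPair(ir_a=ir_a, ir_b=ir_b, length_bp=rep_len, method=method)


def _self_comparison_ir(
    record: GenomeRecord, min_len: int, max_mismatch_frac: float, k: int = 21
) -> Optional[RepeatPair]:
    """Seed-and-extend search for the longest pair of disjoint segments
    whose sequences are reverse complements (allowing a mismatch budget)."""
    seq = record.require_sequence("find_inverted_repeats").upper()
    L = len(seq)
    if L < 2 * min_len or min_len < k:
        if min_len < k:
            k = max(4, min_len // 2)
        if L < 2 * min_len:
            return None
    rc = reverse_complement(seq)

    seeds: dict[str, list[int]] = {}
    for i in range(0, L - k + 1):
        seeds.setdefault(seq[i : i + k], []).append(i)

    # X-drop extension: +1 per match, -MISMATCH_PENALTY per mismatch; stop a
    # direction once the running score falls X_DROP below its best, and end
    # the segment at the best-scoring position.  Inside a true repeat at a
    # small mismatch fraction the score climbs steadily; in flanking random
    # sequence it collapses within a few bases, so boundaries are recovered
    # tightly.  With max_mismatch_frac = 0 any mismatch ends extension
    # immediately and recovery is exact.
    MISMATCH_PENALTY = 4
    X_DROP = 24

    def _extend(p: int, q: int, dp: int, limit: int) -> tuple[int, int]:
        """Walk from (p, q) in direction dp; return (steps, mismatches) to
        the best-scoring endpoint (never ending on a mismatch)."""
        score = best_score = 0
        steps = best_steps = 0
        mis = best_mis = 0
        while 0 <= p < L and 0 <= q < L and steps < limit:
            if seq[p] == rc[q] and seq[p] in "ACGT":
                score += 1
            else:
                if max_mismatch_frac == 0:
                    break
                score -= MISMATCH_PENALTY
                mis += 1
            steps += 1
            if score > best_score:
                best_score, best_steps, best_mis = score, steps, mis
            elif score < best_score - X_DROP:
                break
            p += dp
            q += dp
        return best_steps, best_mis

    best: Optional[tuple[int, int, int]] = None  # (i, j, length) in seq-vs-rc coords
    done_diagonals: dict[int, list[tuple[int, int]]] = {}

    for j in range(0, L - k + 1):
        kmer = rc[j : j + k]
        for i in seeds.get(kmer, ()):  # seed: seq[i:i+k] == rc[j:j+k]
            diag = i - j
            covered = done_diagonals.setdefault(diag, [])
            if any(lo <= i < hi for lo, hi in covered):
                continue
            lsteps, lmis = _extend(i - 1, j - 1, -1, L)
            rsteps, rmis = _extend(i + k, j + k, +1, L)
            li, lj = i - lsteps, j - lsteps
            ri, rj = i + k + rsteps, j + k + rsteps  # exclusive ends
            # enforce the overall mismatch budget by shaving the weaker side
            while lmis + rmis > int(max_mismatch_frac * (ri - li)) and (
                lsteps or rsteps
            ):
                if rmis >= lmis and rsteps:
                    rsteps, rmis = _extend(i + k, j + k, +1, rsteps - 1)
                elif lsteps:
                    lsteps, lmis = _extend(i - 1, j - 1, -1, lsteps - 1)
                else:
                    break
                li, lj = i - lsteps, j - lsteps
                ri, rj = i + k + rsteps, j + k + rsteps
            covered.append((li, ri))
            match_len = ri - li
            if match_len < min_len:
                continue
            # map rc segment [lj, rj) back to forward coordinates
            f2_lo, f2_hi = L - rj, L - lj  # half-open on forward strand
            # require disjoint segments (a self-palindrome is not an IR pair)
            if not (ri <= f2_lo or f2_hi <= li):
                continue
            if best is None or match_len > best[2]:
                best = (li, lj, match_len)

    if best is None:
        return None
    li, lj, n = best
    seg1 = (li + 1, li + n)  # 1-based inclusive
    f2_lo = L - (lj + n)
    seg2 = (f2_lo + 1, f2_lo + n)
    a, b = sorted([seg1, seg2])
    return _orient_pair(a, b, L, "self_comparison")


def find_inverted_repeats(
    record: GenomeRecord,
    method: str = "annotation",
    min_len: int = 1000,
    max_mismatch_frac: float = 0.01,
) -> Optional[RepeatPair]:
    """Locate the canonical inverted-repeat pair of a (plastid) genome.

    ``method="annotation"`` pairs two annotated repeat features whose key or
    notes match the IR vocabulary; ``"self_comparison"`` finds the longest
    reverse-complement-matching pair of disjoint segments de novo by k-mer
    seeding and greedy extension under a mismatch budget; ``"none"``
    disables detection and returns ``None``.
    """
    if method == "none":
        return None
    if method == "annotation":
        if not record.features:
            raise OrgmapError("annotation IR method requires features")
        return _annotation_ir(record)
    if method == "self_comparison":
        return _self_comparison_ir(record, min_len, max_mismatch_frac)
    raise OrgmapError(f"unknown IR method {method!r}")


# ---------------------------------------------------------------------------
# restriction sites


@dataclass(frozen=True)
class CutSite:
    enzyme: str
    position: int  # 1-based first base of the recognition sequence
    strand: str  # "+" | "-"


_ENZYMES: Optional[dict[str, tuple[str, int]]] = None


def load_enzyme_table(extra_path: Optional[str] = None) -> dict[str, tuple[str, int]]:
    """name -> (IUPAC recognition sequence, cut offset); shipped table plus
    optional user extensions from a TSV file of the same three columns."""
    global _ENZYMES
    if _ENZYMES is None:
        table: dict[str, tuple[str, int]] = {}
        text = (
            importlib.resources.files("orgmap").joinpath("data", "enzymes.tsv").read_text()
        )
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, site, offset = line.split("\t")
            table[name] = (site.upper(), int(offset))
        _ENZYMES = table
    table = dict(_ENZYMES)
    if extra_path:
        with open(extra_path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, site, offset = line.split("\t")
                table[name] = (site.upper(), int(offset))
    return table


def _pattern_regex(site: str) -> re.Pattern:
    # Genome-side ambiguity codes never match: classes expand over ACGT only.
    parts = []
    for ch in site:
        bases = IUPAC_SETS.get(ch)
        if bases is None:
            raise OrgmapError(f"recognition sequence has invalid symbol {ch!r}")
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("(?=(" + "".join(parts) + "))")


def scan_restriction_sites(
    record: GenomeRecord,
    enzymes: list[str],
    enzyme_table: Optional[dict[str, tuple[str, int]]] = None,
) -> list[CutSite]:
    """All recognition-site matches of the named enzymes, both strands.

    Positions are the 1-based first base of the recognition sequence on the
    plus strand.  On circular records matches spanning the origin are
    reported at their wrapped start position.  Palindromic sites are
    reported once, on the plus strand.
    """
    seq = record.require_sequence("scan_restriction_sites").upper()
    table = enzyme_table or load_enzyme_table()
    unknown = [e for e in enzymes if e not in table]
    if unknown:
        raise OrgmapError(
            f"unknown enzyme(s) {unknown}; valid names: {', '.join(sorted(table))}"
        )
    L = len(seq)
    sites: list[CutSite] = []
    for name in enzymes:
        site, _offset = table[name]
        m = len(site)
        search_seq = seq + seq[: m - 1] if record.topology == "circular" else seq
        palindromic = reverse_complement(site) == site
        strands = [("+", site)]
        if not palindromic:
            strands.append(("-", reverse_complement(site)))
        for strand, pat in strands:
            pattern = _pattern_regex(pat)
            for match in pattern.finditer(search_seq):
                pos = match.start() + 1
                if pos <= L:
                    sites.append(CutSite(enzyme=name, position=pos, strand=strand))
    sites.sort(key=lambda s: (s.position, s.enzyme, s.strand))
    return sites
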