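"""Synthetic organellar GenBank records with known ground truth.

Every fixture is fully determined by its seed and carries a ground-truth
record of what was planted — features, inverted-repeat boundaries, intron
genes, origin-wrapping features and (brute-force enumerated) restriction
sites — so parser, scanners and layout can be asserted against construction
rather than external data.

Plastome-like fixtures follow the quadripartite architecture
LSC + IR_B + SSC + IR_A, with IR_A the reverse complement of IR_B placed at
the sequence end (so it is the right repeat, adjacent to nucleotide 1).
The generator forces the first SSC base to differ from the complement of
the last SSC base, making the planted repeat non-extendable: exact boundary
recovery is then well defined.  Optional IUPAC noise and planted mismatches
never touch the 25 bp at either repeat boundary.

Gene content is drawn from the same canonical name lexicons the classifier
ships, guaranteeing every fixture gene is classifiable.  Sequences are
i.i.d. random nucleotides: no codon structure, no base-composition skew.
"""

from __future__ import annotations

import io
import random
from dataclasses import dataclass, field
from typing import Optional

from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .feature_model import _data_text
from .model import OrgmapError
from .seq_analysis import IUPAC_SETS, reverse_complement

__all__ = [
    "FixtureSpec",
    "PlantedFeature",
    "GroundTruth",
    "make_fixture",
    "make_multi_fixture",
    "naive_cut_sites",
    "naive_gc_windows",
]

_AMBIGUITY = "NRYKMSWBDHV"


@dataclass
class FixtureSpec:
    kind: str = "generic"  # plastome_like | mitogenome_like | generic
    length_bp: int = 10_000
    ir_len: Optional[int] = None
    n_genes: int = 12
    plant_introns: bool = False
    wrap_origin_feature: bool = False
    iupac_noise_frac: float = 0.0
    seed: int = 0
    topology: str = "circular"
    enzymes: tuple[str, ...] = ("EcoRI",)
    ir_mismatches: int = 0  # planted point mismatches between the IR copies


@dataclass
class PlantedFeature:
    key: str
    parts: tuple[tuple[int, int], ...]
    strand: str = "+"
    gene_name: Optional[str] = None
    wraps_origin: bool = False
    qualifiers: dict[str, str] = field(default_factory=dict)


@dataclass
class GroundTruth:
    accession: str
    organism: str
    length_bp: int
    topology: str
    source_category: str
    features: list[PlantedFeature]
    ir_a: Optional[tuple[int, int]] = None
    ir_b: Optional[tuple[int, int]] = None
    intron_genes: frozenset[str] = frozenset()
    cut_sites: dict[str, list[tuple[int, str]]] = field(default_factory=dict)
    sequence: str = ""


# ---------------------------------------------------------------------------
# brute-force oracles (deliberately naive; used as independent ground truth)


def naive_cut_sites(seq: str, site: str, topology: str) -> list[tuple[int, str]]:
    """Position-by-position IUPAC match of a recognition site, both strands.

    Genome-side ambiguity codes never match.  Palindromic sites are
    reported once, on the plus strand.  O(n*m) by construction.
    """
    seq = seq.upper()
    L = len(seq)
    m = len(site)
    doubled = seq + seq[: m - 1] if topology == "circular" else seq
    palindromic = reverse_complement(site) == site
    patterns = [("+", site)] + ([] if palindromic else [("-", reverse_complement(site))])
    hits = []
    for strand, pat in patterns:
        sets = [IUPAC_SETS[c] for c in pat]
        for p in range(len(doubled) - m + 1):
            if p >= L:
                break
            ok = True
            for q in range(m):
                ch = doubled[p + q]
                if ch not in "ACGT" or ch not in sets[q]:
                    ok = False
                    break
            if ok:
                hits.append((p + 1, strand))
    hits.sort()
    return hits


def naive_gc_windows(
    seq: str, window: int, step: int, topology: str
) -> list[float]:
    """Direct per-window GC counting (S counts GC, W counts AT, the rest of
    the ambiguity codes are excluded entirely)."""
    seq = seq.upper()
    L = len(seq)
    if topology == "circular":
        n = -(-L // step)
        doubled = seq + seq[:window]
    else:
        n = max(1, (L - window) // step + 1) if L >= window else 1
        doubled = seq
    out = []
    for i in range(n):
        w = doubled[i * step : i * step + window]
        gc = sum(1 for c in w if c in "GCS")
        ct = sum(1 for c in w if c in "ACGTSW")
        out.append(gc / ct if ct else 0.0)
    return out


# ---------------------------------------------------------------------------
# generation helpers

_BASES = "ACGT"


def _rand_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choices(_BASES, k=n))


def _load_names(fname: str) -> list[str]:
    return [
        line.strip()
        for line in _data_text(fname).splitlines()
        if line.strip() and not line.startswith("#")
    ]


def _gene_key(name: str) -> str:
    if name.startswith("trn"):
        return "tRNA"
    if name.startswith("rrn"):
        return "rRNA"
    return "CDS"


def _place_genes(
    rng: random.Random,
    regions: list[tuple[int, int]],
    names: list[str],
    plant_introns: bool,
) -> tuple[list[PlantedFeature], frozenset[str]]:
    """Walk each region left to right, dropping non-overlapping genes."""
    feats: list[PlantedFeature] = []
    intron_genes: set[str] = set()
    name_iter = iter(names)
    for reg_start, reg_end in regions:
        cursor = reg_start + rng.randint(20, 120)
        while True:
            try:
                name = next(name_iter)
            except StopIteration:
                return feats, frozenset(intron_genes)
            key = _gene_key(name)
            if key == "tRNA":
                glen = rng.randint(70, 90)
            elif key == "rRNA":
                glen = rng.randint(1200, 1600)
            else:
                glen = rng.randint(300, 1500)
            if cursor + glen > reg_end:
                break
            strand = rng.choice("+-")
            start, end = cursor, cursor + glen - 1
            with_intron = (
                plant_introns and key == "CDS" and glen >= 600 and rng.random() < 0.5
            )
            feats.append(
                PlantedFeature(
                    key="gene", parts=((start, end),), strand=strand, gene_name=name
                )
            )
            if with_intron:
                exon1 = rng.randint(150, glen // 2 - 50)
                intron_len = rng.randint(100, glen - exon1 - 100)
                parts = (
                    (start, start + exon1 - 1),
                    (start + exon1 + intron_len, end),
                )
                intron_genes.add(name)
            else:
                parts = ((start, end),)
            feats.append(
                PlantedFeature(key=key, parts=parts, strand=strand, gene_name=name)
            )
            cursor = end + 1 + rng.randint(40, 250)
    return feats, frozenset(intron_genes)


def _apply_noise(
    rng: random.Random, seq: list[str], frac: float, protected: list[tuple[int, int]]
) -> None:
    """Replace a fraction of bases with IUPAC ambiguity codes, in place.
    ``protected`` intervals (0-based half-open) are never touched."""
    n = int(len(seq) * frac)
    forbidden = set()
    for lo, hi in protected:
        forbidden.update(range(lo, hi))
    placed = 0
    while placed < n:
        p = rng.randrange(len(seq))
        if p in forbidden or seq[p] not in _BASES:
            continue
        seq[p] = rng.choice(_AMBIGUITY)
        placed += 1


# ---------------------------------------------------------------------------
# main entry


def make_fixture(spec: FixtureSpec) -> tuple[str, GroundTruth]:
    """Generate one synthetic GenBank record plus its ground truth.

    The emitted text is a valid flat file (LOCUS/FEATURES/ORIGIN//) written
    through Biopython and re-readable by :mod:`orgmap.genbank_io`; calling
    twice with the same spec yields byte-identical output.
    """
    rng = random.Random(spec.seed)
    L = spec.length_bp
    if L < 1200:
        raise OrgmapError("fixture length must be >= 1200 bp")

    planted: list[PlantedFeature] = []
    ir_a = ir_b = None
    organism = "Synthetica genericae"
    source_cat = "other"
    division = "UNA"
    organelle = None

    if spec.kind == "plastome_like":
        r = spec.ir_len or max(1000, L // 10)
        if 2 * r >= L - 400:
            raise OrgmapError(f"ir_len {r} too large for length {L}")
        ssc_len = max(200, (L - 2 * r) // 5)
        lsc_len = L - 2 * r - ssc_len
        lsc = _rand_seq(rng, lsc_len)
        ir = _rand_seq(rng, r)
        ssc = list(_rand_seq(rng, ssc_len))
        # make the planted repeat non-extendable inward
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        if ssc[0] == comp[ssc[-1]]:
            ssc[0] = _BASES[(_BASES.index(ssc[0]) + 1) % 4]
        seq_list = list(lsc + ir + "".join(ssc) + reverse_complement(ir))
        ir_b = (lsc_len + 1, lsc_len + r)
        ir_a = (L - r + 1, L)
        if spec.ir_mismatches:
            # planted point noise in one repeat copy, clear of boundaries
            for _ in range(spec.ir_mismatches):
                p = rng.randint(ir_b[0] + 25, ir_b[1] - 26)
                old = seq_list[p - 1]
                seq_list[p - 1] = rng.choice([b for b in _BASES if b != old])
        organism = "Synthetica plastomica"
        source_cat = "plastid"
        division = "PLN"
        organelle = "plastid:chloroplast"
        names = [n for n in _load_names("plastid_genes.txt")]
        rng.shuffle(names)
        gene_regions = [(1, lsc_len - 50), (lsc_len + r + 1, lsc_len + r + ssc_len - 50)]
        feats, intron_genes = _place_genes(
            rng, gene_regions, names[: spec.n_genes], spec.plant_introns
        )
        planted.extend(feats)
        planted.append(
            PlantedFeature(
                key="repeat_region",
                parts=(ir_b,),
                strand="+",
                qualifiers={"note": "inverted repeat B", "rpt_type": "inverted"},
            )
        )
        planted.append(
            PlantedFeature(
                key="repeat_region",
                parts=(ir_a,),
                strand="+",
                qualifiers={"note": "inverted repeat A", "rpt_type": "inverted"},
            )
        )
        protected = [(ir_b[0] - 2, ir_b[1] + 1), (ir_a[0] - 2, ir_a[1] + 1)]
    elif spec.kind == "mitogenome_like":
        seq_list = list(_rand_seq(rng, L))
        organism = "Synthetica mitochondriae"
        source_cat = "mitochondrial"
        division = "INV"
        organelle = "mitochondrion"
        names = _load_names("mito_genes.txt")
        rng.shuffle(names)
        dloop_margin = 420
        feats, intron_genes = _place_genes(
            rng,
            [(dloop_margin, L - dloop_margin)],
            names[: spec.n_genes],
            spec.plant_introns,
        )
        planted.extend(feats)
        if spec.wrap_origin_feature:
            planted.append(
                PlantedFeature(
                    key="D-loop",
                    parts=((L - 399, L), (1, 300)),
                    strand="+",
                    wraps_origin=True,
                )
            )
        else:
            planted.append(
                PlantedFeature(key="D-loop", parts=((1, 400),), strand="+")
            )
        protected = []
    elif spec.kind == "generic":
        seq_list = list(_rand_seq(rng, L))
        names = _load_names("plastid_genes.txt")
        rng.shuffle(names)
        margin = 350 if spec.wrap_origin_feature else 0
        feats, intron_genes = _place_genes(
            rng, [(margin + 1, L - margin)], names[: spec.n_genes], spec.plant_introns
        )
        planted.extend(feats)
        if spec.wrap_origin_feature:
            planted.append(
                PlantedFeature(
                    key="gene",
                    parts=((L - 299, L), (1, 200)),
                    strand="+",
                    gene_name="ycf1",
                    wraps_origin=True,
                )
            )
        protected = []
    else:
        raise OrgmapError(f"unknown fixture kind {spec.kind!r}")

    if spec.iupac_noise_frac:
        _apply_noise(rng, seq_list, spec.iupac_noise_frac, protected)
    sequence = "".join(seq_list)

    accession = f"SYN{spec.kind[:2].upper()}{spec.seed % 100000:05d}"
    truth = GroundTruth(
        accession=accession,
        organism=organism,
        length_bp=L,
        topology=spec.topology,
        source_category=source_cat,
        features=[],
        ir_a=ir_a,
        ir_b=ir_b,
        intron_genes=intron_genes,
        cut_sites={},
        sequence=sequence,
    )
    for enzyme in spec.enzymes:
        from .seq_analysis import load_enzyme_table

        site, _ = load_enzyme_table()[enzyme]
        truth.cut_sites[enzyme] = naive_cut_sites(sequence, site, spec.topology)

    # source feature first, then planted features in coordinate order
    src = PlantedFeature(
        key="source",
        parts=((1, L),),
        strand="+",
        qualifiers={"organism": organism}
        | ({"organelle": organelle} if organelle else {}),
    )
    planted.sort(key=lambda f: (f.parts[0][0], f.key))
    truth.features = [src] + planted

    record = _to_seqrecord(truth, sequence, division)
    buf = io.StringIO()
    SeqIO.write(record, buf, "genbank")
    return buf.getvalue(), truth


def _to_seqrecord(truth: GroundTruth, sequence: str, division: str) -> SeqRecord:
    rec = SeqRecord(Seq(sequence), id=truth.accession, name=truth.accession)
    what = {
        "plastid": "chloroplast",
        "mitochondrial": "mitochondrion",
        "other": "replicon",
    }[truth.source_category]
    rec.description = f"{truth.organism} {what}, complete genome"
    rec.annotations.update(
        {
            "molecule_type": "DNA",
            "topology": truth.topology,
            "data_file_division": division,
            "date": "01-JAN-2020",
            "organism": truth.organism,
            "source": f"{what} {truth.organism}",
            "accessions": [truth.accession],
        }
    )
    strand_of = {"+": 1, "-": -1}
    for pf in truth.features:
        locs = [
            SimpleLocation(s - 1, e, strand=strand_of[pf.strand])
            for s, e in pf.parts
        ]
        location = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        feat = SeqFeature(location, type=pf.key)
        if pf.gene_name:
            feat.qualifiers["gene"] = [pf.gene_name]
        for k, v in pf.qualifiers.items():
            feat.qualifiers[k] = [v]
        rec.features.append(feat)
    return rec


def make_multi_fixture(specs: list[FixtureSpec]) -> tuple[str, list[GroundTruth]]:
    """Concatenate several fixtures into one multi-GenBank file."""
    texts, truths = [], []
    for spec in specs:
        text, truth = make_fixture(spec)
        texts.append(text)
        truths.append(truth)
    return "".join(texts), truths
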