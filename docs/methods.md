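# Methods

This note records how `orgmap` computes what it draws: the conventions,
the algorithms, the defaults and why they are what they are, and what the
synthetic-fixture test regime does and does not demonstrate.

## Coordinate model and drawing conventions

All genomic coordinates in the data model are 1-based inclusive, the
GenBank feature-table convention; only the geometry code converts to other
forms. A feature is an ordered list of `(start, end)` parts; a feature
that spans the sequence origin keeps its parts in reading order and is
flagged `wraps_origin` (detected as a coordinate restart between
consecutive parts, e.g. `join(9000..10000,1..500)`).

Circular maps place nucleotide 1 at 0°, i.e. 3 o'clock, with angles
growing clockwise: `angle(pos) = 360·(pos−1)/L`. Plus-strand features are
drawn inside the baseline circle (transcribed clockwise), minus-strand
features outside; linear maps mirror this above/below the axis. An
origin-spanning feature is one continuous arc whose stored
`start + extent` exceeds 360° — deliberately not normalized, so the
crossing is explicit. The inverted repeat designated IR_A is the copy
whose end is closest (clockwise) to nucleotide 1, i.e. the right repeat on
the map; this matches the usual convention that position 1 begins the
large single-copy region immediately after IR_A.

Linear maps use `x(pos) = stretch · (pos − window_start)` with
`stretch = canvas_width / window_length` unless overridden, so the drawn
window always fills the canvas exactly; zoom is a linear-map feature and
is rejected on circular layouts. Features are clipped to the window and
clipped edges flagged in element metadata.

## Gene classification and tidy-up

Classes ship as a versioned JSON table per source category (plastid,
mitochondrial, generic), each with a label, a `#RRGGBB` color, gene-name
patterns and/or feature keys. Classification is first-match: per-gene
override from the XML configuration, then gene-name patterns in table
order, then feature-key rules (`tRNA`→trna, `rRNA`→rrna, `D-loop`→dloop,
`prim_transcript`/`operon`→operon, …), then the catch-all class. The
default palette is this package's own choice and fully overridable.

Tidy-up rejects names longer than 20 characters after trimming (no
legitimate organellar locus tag approaches that; threshold configurable)
and otherwise normalizes: canonical casing from a shipped lexicon of
plastid and mitochondrial locus tags (`PSBA`→`psbA`, `rpoc1`→`rpoC1`),
and the hyphenated tRNA form `trnX-ANT` with an uppercase RNA anticodon.
The transformation is idempotent and never lengthens a name (a separator
is converted, never inserted). The lexicon is data, shared with the
fixture generator so every generated gene is classifiable, and
user-extensible.

A gene *has an intron* when its own location (or that of a CDS/tRNA/rRNA
of the same gene name) has ≥2 non-wrapping parts, or an `intron` feature
lies within its extent. Origin wrapping is explicitly not an intron. In
the default asterisk style the label gains a `*`; in box style the exon
parts are drawn with empty gap boxes between them (taking the exon
structure from the CDS twin when the `gene` feature itself is a single
span).

## Sequence analyses

**GC profile.** Windows of `window_bp` at `step_bp` intervals; on circular
records windows wrap the origin and there are exactly `ceil(L/step)` of
them. The fraction is `(G+C+S) / (A+C+G+T+S+W)`: S *is* strong (G/C) and W
*is* weak (A/T), while all other ambiguity codes carry no G/C information
and are excluded from numerator and denominator alike. A window with no
countable base reports 0. Implemented with cumulative sums; the test
oracle recounts every window directly.

**Restriction scanning.** The shipped table (~65 enzymes, TSV:
name, IUPAC site, cut offset) is user-extensible. Patterns are expanded
over `ACGT` only, so an ambiguity code in the *genome* never satisfies a
match — conservative and reproducible. Both strands are scanned
(palindromic sites reported once, plus strand), overlapping matches are
found, and circular records are scanned across the origin with positions
reported at the wrapped start. The oracle is a position-by-position O(n·m)
matcher.

**Inverted repeats.** Two methods. *Annotation*: pair the two largest
features whose key/notes match the IR vocabulary (`repeat_region`,
`/rpt_type="inverted"`, notes containing "inverted repeat", "IRa/IRb",
"IR-A/IR-B"). *Self-comparison*: exact 21-mer seeds between the forward
sequence and its reverse complement, extended per seed by X-drop
(match +1, mismatch −4, drop 24, endpoint at the best score so extension
never ends on a mismatch), with the overall mismatch fraction capped at
`max_mismatch_frac` by shaving the weaker side. Defaults
`min_len = 1000 bp`, `max_mismatch_frac = 0.01`. With
`max_mismatch_frac = 0` any mismatch stops extension and planted repeats
are recovered to the base. Only the longest disjoint pair is returned —
the canonical IR, not a dispersed-repeat search. Matching is performed in
linear coordinates; a repeat pair whose copies themselves span the origin
would be truncated at position 1 (not a configuration that occurs in the
conventional plastome architecture, where position 1 starts the LSC).

## Rendering

The layout (arcs, boxes, gaps, ticks, label anchors with tier assignments,
GC/scale/IR rings) is pure data in abstract map units (canvas 1000×1000
for circular maps, 100 units per inch when rasterizing). Labels are
placed by a deterministic greedy pass in coordinate order: a label
colliding with an already-placed one on its side and tier moves outward
one tier and gets a leader line; labels are never dropped. Label extents
use a fixed abstract character advance so placement is reproducible
across systems; at render time fonts fall back to the viewer's sans-serif.

The SVG writer is the reference backend: stable element order, floats
fixed at three decimals, no timestamps — identical layouts give
byte-identical files, which the batch driver re-verifies end to end.
PDF, PostScript and the raster formats are drawn from the *same layout
object* through matplotlib (JPEG quality 92, LZW-compressed TIFF), so all
formats show the same geometry; the raster pixel width is
`canvas_width/100 × dpi`. Vector text placement may differ sub-point
between backends, which is why byte-determinism is guaranteed for SVG
specifically.

## Transcript mode

Expression tables are two-column (gene, signed value) TSV/CSV with an
optional header; duplicates last-win with a warning. Colors ramp linearly
from a neutral grey at 0 toward the up- or down-regulation hue,
saturating at `max_abs` (default: the dataset's largest |value|), so the
map is symmetric in sign and monotone in magnitude. Expression is drawn
as an overlay ring of per-gene boxes outside the gene arcs — geometry is
never altered, and genes absent from the dataset get neutral boxes. (The
alternative of recoloring the gene arcs themselves was rejected to keep
the functional-class colors legible.)

## The synthetic-fixture regime

`orgmap.fixtures` generates GenBank records whose ground truth is known by
construction: every planted feature, the IR boundaries, intron genes and
brute-force-enumerated cut sites. Plastome-like fixtures follow the
LSC + IR_B + SSC + IR_A architecture with IR_A = revcomp(IR_B) at the
sequence end; mitogenome-like fixtures are compact with a D-loop that can
span the origin; gene names come from the shipped lexicons. A fixture is
fully determined by its seed (no global random state), and two details
make recovery assertions exact: the first SSC base is forced to differ
from the complement of the last SSC base, so the planted repeat cannot be
extended by chance, and optional repeat noise (for the mismatch-budget
tests) keeps 25 bp at each boundary clean — hence the noisy-recovery
tolerance of 25 bp used in the tests.

Fixture sequences are i.i.d. uniform nucleotides: no codon structure, no
GC skew, no nested or partially duplicated genes, no dispersed repeats,
and annotation follows the writer's own formatting. Passing tests
therefore demonstrate the correctness of coordinate handling, scanning,
geometry and rendering — not robustness to the full messiness of
hand-curated GenBank submissions (inconsistent qualifiers, nonstandard
keys, contradictory topology evidence). Where such conflicts are
detectable (e.g. a linear LOCUS with an origin-wrapping feature) the
parser keeps the record's stated value and logs the conflict.

Test and acceptance population sizes (1000 round-trip fixtures drawn
log-uniformly over 2–160 kb — plastome-like ones over 12–160 kb so the
quadripartite architecture fits; 1000 scanner fixtures at 2–5 kb; 200 IR
fixtures at 20–40 kb with 2–4 kb repeats) are the package's own choices:
log-uniform reflects that small replicons vastly outnumber plastome-scale
ones, and the IR sizes scale the plastome architecture down
proportionally while keeping detection non-trivial.

## Known limitations

- EMBL/GFF3 input, network fetch and full INSDC vocabulary validation are
  out of scope; input is the GenBank flat-file grammar.
- IR detection returns at most one pair (the canonical plastome IR);
  dispersed repeats and repeat families are not searched.
- Restriction tables are a curated subset, not a REBASE import; cut
  offsets are carried but only recognition sites are drawn.
- Label placement optimizes nothing beyond the deterministic greedy pass;
  extremely dense maps may stack many tiers.
- Expression overlays support a single condition; multi-condition heat
  tracks are not implemented.
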