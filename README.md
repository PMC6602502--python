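# orgmap

Publication-grade physical maps of organellar genomes, drawn straight from
GenBank flat files.

Plastid and mitochondrial genomes are small, densely annotated replicons,
and the standard way to present one is a circular (or linear) map: gene
arcs colored by functional class, plus-strand genes inside the circle
(transcribed clockwise) and minus-strand genes outside, a GC-content ring
with a reference circle at the 50% threshold, brackets over the large
inverted repeats of plastomes, and optional restriction-site ticks.
`orgmap` is a library and command-line tool that produces such maps for
anyone annotating, comparing or publishing organellar genomes — no web
service, no database, just GenBank in, SVG/PDF/PNG out.

## What it does

- **Parses (multi-)GenBank flat files**, resolving `join`/`complement`
  locations, origin-spanning features, fuzzy positions and IUPAC ambiguity
  characters; genome conformation (circular/linear) and sequence source
  (plastid/mitochondrial/other) are taken from the record itself.
- **Classifies genes** into the standard functional classes (photosystems,
  cytochrome complex, ATP synthase, NADH dehydrogenase, ribosomal proteins,
  respiratory-chain complexes I–V, tRNA, rRNA, D-loop, …) with a tidy-up
  pass that rejects over-long gene names and normalizes nomenclature
  (`PSBA` → `psbA`, `trnh gug` → `trnH-GUG`). An XML configuration file can
  recolor classes, rename products, or make extra feature keys drawable.
- **Sequence analyses.** Sliding-window GC content with origin-wrapping
  windows; inverted-repeat detection either from `repeat_region`
  annotation or de novo by seed-and-extend self-comparison; degenerate
  restriction-site scanning against a shipped table of ~65 enzymes.
  Position 1 sits at 3 o'clock; IR\_A is drawn as the right repeat, the
  copy ending at nucleotide 1.
- **Geometry before pixels.** A resolution-independent layout (arc angles
  exact to `360·len/L`, deterministic greedy label placement, linear maps
  with an exact fill-the-canvas stretch factor and zoom windows) is
  rendered to byte-deterministic SVG, and to PDF/PS/PNG/TIFF/JPEG at any
  resolution.
- **Transcript mode** overlays per-gene expression values (e.g. log2 fold
  changes) as up/down-colored boxes with a saturation ramp.
- **Batch processing**: many files, multi-record files, per-record error
  isolation, job log, optional zip bundle of all outputs.

Intron-containing genes are marked with an asterisk by default; the
classic alternative of drawing introns as empty boxes inside genes is
available (`--intron-style box`). Polycistronic transcription units
annotated as `prim_transcript` or `operon` are drawn as bars, and the
D-loop of metazoan mitochondrial genomes is drawn by default — even when
it spans the sequence origin.

## Worked example

The package ships a synthetic-record generator (used throughout the test
suite), so a full demonstration needs no downloads:

```python
from orgmap.fixtures import FixtureSpec, make_fixture

text, truth = make_fixture(FixtureSpec(
    kind="plastome_like", length_bp=140_000, ir_len=24_000,
    n_genes=60, plant_introns=True, seed=4))
open("demo_plastome.gb", "w").write(text)
```

```bash
$ orgmap demo_plastome.gb --ir self --enzymes EcoRI,HindIII \
        --format svg,png --out demo_maps
SYNPL00004: ok
1/1 records rendered -> demo_maps
```

The same record through the library:

```python
from orgmap import read_genbank, find_inverted_repeats, gc_profile

r = read_genbank("demo_plastome.gb")[0]
print(f"{r.accession}: {r.length_bp:,} bp {r.topology} {r.source_category}, "
      f"{len(r.features)} features")
ir = find_inverted_repeats(r, "self_comparison")
print(f"IR pair: IRA {ir.ir_a}, IRB {ir.ir_b}, {ir.length_bp:,} bp")
prof = gc_profile(r, 350, 350)
print(f"GC windows: {len(prof.values)}, "
      f"mean GC {sum(v for _, v in prof.values)/len(prof.values):.3f}")
```

prints

```
SYNPL00004: 140,000 bp circular plastid, 123 features
IR pair: IRA (116001, 140000), IRB (73601, 97600), 24,000 bp
GC windows: 400, mean GC 0.500
```

`SYNPL00004` is a quadripartite plastome: LSC, a 24 kb inverted repeat
pair found de novo with exactly the planted boundaries (IRA is the copy
ending at position 140,000, adjacent to nucleotide 1), and the mean GC of
an i.i.d. random sequence is 0.5 as expected. `demo_maps/` holds the
circular map as `SYNPL00004.svg`/`.png` plus a `job.log`.

Common flags: `--mode standard|transcript`, `--tidy/--no-tidy`,
`--shape auto|circular|linear`, `--ir annotation|self|off`,
`--gc/--no-gc`, `--zoom START:END` (linear), `--intron-style
asterisk|box`, `--config conf.xml`, `--expression table.tsv`,
`--up-color/--down-color`, `--format svg,pdf,png,...`, `--dpi N`,
`--zip`.

## Layout of the code

| module | role |
| --- | --- |
| `orgmap.genbank_io` | GenBank flat files → `GenomeRecord` |
| `orgmap.feature_model` | classes, tidy-up, XML configuration |
| `orgmap.seq_analysis` | GC profile, IR detection, restriction scan |
| `orgmap.layout` | resolution-independent map geometry |
| `orgmap.render` | SVG writer + PDF/PS/raster backends |
| `orgmap.transcript_mode` | expression tables and recoloring |
| `orgmap.fixtures` | synthetic records with ground truth |
| `orgmap.cli` | batch driver and `orgmap` command |

See `docs/methods.md` for the algorithms, parameter defaults and known
limitations.
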