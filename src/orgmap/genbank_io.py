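"""Reading GenBank flat files into :class:`~orgmap.model.GenomeRecord`.

Parsing is delegated to Biopython's GenBank parser; this module adapts the
result to the package's 1-based data model, resolves topology and sequence
source, flags origin-spanning compound locations, and clamps fuzzy
positions (``<``, ``>``) to their numeric bounds with a warning.
"""

from __future__ import annotations

import io
import logging
import os
from typing import Iterable, TextIO, Union

from Bio import SeqIO
from Bio.Seq import UndefinedSequenceError
from Bio.SeqFeature import AfterPosition, BeforePosition, SeqFeature

from .model import FeatureInstance, FeatureLocation, GenomeRecord, OrgmapError

logger = logging.getLogger(__name__)

__all__ = ["read_genbank", "resolve_topology_and_source", "GenBankParseError"]


class GenBankParseError(OrgmapError):
    """A GenBank record could not be parsed.

    Carries the 0-based index of the offending record within the file so a
    batch driver can report it precisely.
    """

    def __init__(self, record_index: int, message: str):
        super().__init__(f"record {record_index}: {message}")
        self.record_index = record_index


def _clamp_position(pos, record_name: str) -> int:
    """Return the numeric bound of a possibly fuzzy Biopython position."""
    if isinstance(pos, (BeforePosition, AfterPosition)):
        logger.warning(
            "%s: fuzzy position %s clamped to its numeric bound", record_name, pos
        )
    return int(pos)


def _convert_location(feature: SeqFeature, record_name: str) -> FeatureLocation:
    loc = feature.location
    parts = []
    for part in loc.parts:
        start = _clamp_position(part.start, record_name) + 1  # to 1-based
        end = _clamp_position(part.end, record_name)
        if end < start:  # zero-width fuzzy artifact; clamp to 1 bp
            end = start
        parts.append((start, end))
    strand = "-" if loc.strand == -1 else "+"
    # A compound location whose parts restart at a lower coordinate spans
    # the record origin (e.g. join(9000..10000,1..500)).
    wraps = any(parts[i + 1][0] < parts[i][0] for i in range(len(parts) - 1))
    return FeatureLocation(parts=tuple(parts), strand=strand, wraps_origin=wraps)


def _convert_record(rec, index: int) -> GenomeRecord:
    try:
        sequence = str(rec.seq).upper()
    except UndefinedSequenceError:
        sequence = ""
    length = len(rec.seq) if rec.seq is not None else 0
    if length == 0 and sequence:
        length = len(sequence)
    if length == 0:
        raise GenBankParseError(index, "record has zero length")

    features: list[FeatureInstance] = []
    for feat in rec.features:
        if feat.location is None:
            raise GenBankParseError(
                index, f"feature {feat.type!r} has an unparseable location"
            )
        quals = {k: "; ".join(map(str, v)) for k, v in feat.qualifiers.items()}
        floc = _convert_location(feat, rec.name)
        for start, end in floc.parts:
            if end > length:
                raise GenBankParseError(
                    index,
                    f"feature {feat.type!r} coordinate {end} exceeds record "
                    f"length {length}",
                )
        features.append(
            FeatureInstance(
                key=feat.type,
                location=floc,
                gene_name=quals.get("gene"),
                product=quals.get("product"),
                raw_qualifiers=quals,
            )
        )

    record = GenomeRecord(
        accession=rec.id if rec.id and rec.id != "<unknown id>" else rec.name,
        organism=rec.annotations.get("organism", ""),
        length_bp=length,
        sequence=sequence,
        features=features,
        definition=rec.description or "",
    )
    record.raw_annotations = dict(rec.annotations)  # type: ignore[attr-defined]
    return resolve_topology_and_source(record)


def read_genbank(
    stream_or_path: Union[str, os.PathLike, TextIO]
) -> list[GenomeRecord]:
    """Parse a (multi-)GenBank flat file into a list of records, in file order.

    IUPAC ambiguity characters in the ORIGIN block are preserved verbatim.
    Records without an ORIGIN block yield an empty ``sequence``; operations
    that need sequence raise a structured error later, on request.

    Raises
    ------
    GenBankParseError
        On a malformed LOCUS line, an unterminated record, or a location
        that cannot be interpreted; never silently skips a record.
    """
    if isinstance(stream_or_path, (str, os.PathLike)):
        handle: TextIO = open(stream_or_path)  # noqa: SIM115 - closed below
        close = True
    else:
        handle = stream_or_path
        close = False
    try:
        records: list[GenomeRecord] = []
        parser = SeqIO.parse(handle, "genbank")
        index = 0
        while True:
            try:
                rec = next(parser)
            except StopIteration:
                break
            except ValueError as exc:
                raise GenBankParseError(index, str(exc)) from exc
            records.append(_convert_record(rec, index))
            index += 1
        if not records:
            raise GenBankParseError(0, "no GenBank records found (missing LOCUS?)")
        return records
    finally:
        if close:
            handle.close()


def read_genbank_string(text: str) -> list[GenomeRecord]:
    """Convenience wrapper: parse GenBank flat-file text held in a string."""
    return read_genbank(io.StringIO(text))


_PLASTID_WORDS = ("chloroplast", "plastid")
_MITO_WORDS = ("mitochondrion", "mitochondrial")


def resolve_topology_and_source(record: GenomeRecord) -> GenomeRecord:
    """Fill in ``topology`` and ``source_category`` from record evidence.

    Topology comes from the LOCUS line token (default linear).  Source
    category is inferred from the ``/organelle`` qualifier of the source
    feature first, then from a case-insensitive keyword scan of the
    DEFINITION and SOURCE/ORGANISM text; otherwise ``other``.  Both fields
    remain plain attributes the caller may override.
    """
    annotations = getattr(record, "raw_annotations", {})
    topo = str(annotations.get("topology", "")).lower()
    record.topology = "circular" if topo == "circular" else "linear"

    category = None
    for feat in record.features:
        if feat.key == "source":
            organelle = feat.raw_qualifiers.get("organelle", "").lower()
            if any(w in organelle for w in _PLASTID_WORDS):
                category = "plastid"
            elif any(w in organelle for w in _MITO_WORDS):
                category = "mitochondrial"
            break
    if category is None:
        blob = " ".join(
            [record.definition, record.organism, str(annotations.get("source", ""))]
        ).lower()
        if any(w in blob for w in _PLASTID_WORDS):
            category = "plastid"
        elif any(w in blob for w in _MITO_WORDS):
            category = "mitochondrial"
    record.source_category = category or "other"

    if record.topology == "linear" and any(
        f.location.wraps_origin for f in record.features
    ):
        logger.warning(
            "%s: LOCUS says linear but a feature wraps the origin; "
            "keeping the LOCUS topology",
            record.accession,
        )
    return record
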