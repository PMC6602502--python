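"""Core data model for organellar genome maps.

Coordinates are 1-based inclusive everywhere in this model, following the
GenBank feature-table convention.  Conversion to half-open or angular
coordinates is confined to the geometry code in :mod:`orgmap.layout`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


class OrgmapError(Exception):
    """Base class for all structured errors raised by this package."""


class SequenceRequiredError(OrgmapError):
    """An operation needs nucleotide sequence but the record has none."""

    def __init__(self, operation: str, accession: str = "?"):
        super().__init__(
            f"sequence required: record {accession} has no ORIGIN sequence, "
            f"needed by {operation}"
        )
        self.operation = operation


@dataclass(frozen=True)
class FeatureLocation:
    """Location of one feature as ordered 1-based inclusive parts.

    A feature that spans the sequence origin of a circular (or, per the
    GenBank file, nominally linear) record is stored as two or more parts
    with ``wraps_origin`` set; within each individual part start <= end.
    """

    parts: tuple[tuple[int, int], ...]
    strand: str = "+"  # "+" or "-"
    wraps_origin: bool = False

    def __post_init__(self):
        if not self.parts:
            raise ValueError("FeatureLocation needs at least one part")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for start, end in self.parts:
            if start < 1:
                raise ValueError(f"coordinates are 1-based, got start={start}")
            if end < start:
                raise ValueError(f"part with start {start} > end {end}")

    @property
    def start(self) -> int:
        """First base of the feature in reading order of the parts."""
        return self.parts[0][0]

    @property
    def end(self) -> int:
        """Last base of the feature in reading order of the parts."""
        return self.parts[-1][1]

    @property
    def span_length(self) -> int:
        """Total number of bases covered by the parts."""
        return sum(e - s + 1 for s, e in self.parts)

    def extent(self, length_bp: int) -> tuple[int, int, int]:
        """Drawable extent ``(first, last, span)`` of the feature union.

        For an origin-wrapping location the span runs from the first part's
        start, through position ``length_bp``, to the last part's end.
        """
        if self.wraps_origin:
            first = self.parts[0][0]
            last = self.parts[-1][1]
            span = (length_bp - first + 1) + last
            return first, last, span
        first = min(s for s, _ in self.parts)
        last = max(e for _, e in self.parts)
        return first, last, last - first + 1


@dataclass
class FeatureInstance:
    """One annotation from a GenBank feature table."""

    key: str
    location: FeatureLocation
    gene_name: Optional[str] = None
    product: Optional[str] = None
    raw_qualifiers: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.key:
            raise ValueError("feature key must be non-empty")


@dataclass
class GenomeRecord:
    """One parsed GenBank record.

    ``sequence`` may be empty when the record had no ORIGIN block; sequence-
    dependent operations then raise :class:`SequenceRequiredError`.
    """

    accession: str
    organism: str
    length_bp: int
    topology: str = "linear"  # "circular" | "linear"
    source_category: str = "other"  # "plastid" | "mitochondrial" | "other"
    sequence: str = ""
    features: list[FeatureInstance] = field(default_factory=list)
    definition: str = ""

    def __post_init__(self):
        if self.length_bp < 1:
            raise ValueError("length_bp must be positive")
        if self.sequence and len(self.sequence) != self.length_bp:
            raise ValueError(
                f"length_bp={self.length_bp} != len(sequence)={len(self.sequence)}"
            )
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"bad topology {self.topology!r}")
        if self.source_category not in ("plastid", "mitochondrial", "other"):
            raise ValueError(f"bad source_category {self.source_category!r}")

    def require_sequence(self, operation: str) -> str:
        if not self.sequence:
            raise SequenceRequiredError(operation, self.accession)
        return self.sequence
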