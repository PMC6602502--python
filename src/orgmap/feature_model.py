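"""Feature classification, gene-name tidy-up, and map configuration.

The drawable gene classes (photosystems, ATP synthase, respiratory-chain
complexes, tRNA, rRNA, ...) ship as a versioned data table together with a
canonical gene-name lexicon; both can be overridden by an XML configuration
file (schema in ``data/ogconfig.xsd``).
"""

from __future__ import annotations

import fnmatch
import importlib.resources
import json
import logging
import re
from dataclasses import dataclass, field, replace
from typing import IO, Optional, Union

from lxml import etree

from .model import FeatureInstance, GenomeRecord, OrgmapError

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureClass",
    "MapConfig",
    "ClassifiedFeature",
    "ConfigError",
    "default_config",
    "load_xml_config",
    "tidy_gene_name",
    "classify_feature",
    "classify_features",
]

_HEX_COLOR = re.compile(r"^#[0-9A-Fa-f]{6}$")

#: Default length threshold above which tidy-up rejects a gene name as a
#: likely free-text annotation error.  No legitimate organellar locus tag
#: approaches this length.
TIDY_MAX_LEN = 20


class ConfigError(OrgmapError):
    """Invalid map configuration (XML or programmatic)."""


@dataclass
class FeatureClass:
    """One drawable gene/feature class with its legend color."""

    class_id: str
    display_label: str
    color: str
    member_patterns: tuple[str, ...] = ()
    member_keys: tuple[str, ...] = ()
    enabled: bool = True

    def __post_init__(self):
        if not _HEX_COLOR.match(self.color):
            raise ConfigError(
                f"class {self.class_id!r}: color {self.color!r} is not #RRGGBB"
            )


@dataclass
class MapConfig:
    """Resolved drawing configuration.

    ``zoom`` applies to linear maps only and is validated against the target
    record at draw time.  In transcript mode ``enabled_genes`` (when set)
    restricts drawing to single genes; standard mode toggles whole classes.
    """

    mode: str = "standard"  # "standard" | "transcript"
    classes: list[FeatureClass] = field(default_factory=list)
    tidy_up: bool = True
    tidy_max_len: int = TIDY_MAX_LEN
    intron_style: str = "asterisk"  # "asterisk" | "box"
    ir_method: str = "annotation"  # "annotation" | "self_comparison" | "none"
    enzymes: tuple[str, ...] = ()
    show_gc: bool = True
    zoom: Optional[tuple[int, int]] = None
    stretch_factor: Optional[float] = None
    up_color: str = "#CC0000"
    down_color: str = "#0033CC"
    output_formats: tuple[str, ...] = ("svg",)
    dpi: int = 300
    # per-gene overrides (XML <gene .../> and transcript-mode selection)
    gene_colors: dict[str, str] = field(default_factory=dict)
    gene_products: dict[str, str] = field(default_factory=dict)
    gene_classes: dict[str, str] = field(default_factory=dict)
    key_classes: dict[str, str] = field(default_factory=dict)
    enabled_genes: Optional[frozenset[str]] = None

    def class_by_id(self, class_id: str) -> Optional[FeatureClass]:
        for cls in self.classes:
            if cls.class_id == class_id:
                return cls
        return None

    def copy(self) -> "MapConfig":
        cfg = replace(self)
        cfg.classes = [replace(c) for c in self.classes]
        cfg.gene_colors = dict(self.gene_colors)
        cfg.gene_products = dict(self.gene_products)
        cfg.gene_classes = dict(self.gene_classes)
        cfg.key_classes = dict(self.key_classes)
        return cfg


@dataclass
class ClassifiedFeature:
    """A feature resolved to exactly one drawable class.

    ``gene_id`` is the tidied gene name (the stable identity expression
    datasets and per-gene overrides key on); ``display_name`` is what the
    map label shows and may differ (product rename, intron asterisk).
    """

    feature: FeatureInstance
    class_id: str
    display_name: str
    gene_id: Optional[str] = None
    has_intron: bool = False
    suppressed: bool = False
    #: exon structure for intron-containing genes whose own location is a
    #: single span (the gene/CDS split common in real annotations)
    exon_parts: Optional[tuple[tuple[int, int], ...]] = None


# ---------------------------------------------------------------------------
# built-in tables


def _data_text(name: str) -> str:
    return (
        importlib.resources.files("orgmap").joinpath("data", name).read_text()
    )


def _load_lexicon() -> dict[str, str]:
    """casefolded name -> canonical casing, from the shipped lexicons."""
    table: dict[str, str] = {}
    for fname in ("plastid_genes.txt", "mito_genes.txt"):
        for line in _data_text(fname).splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                table.setdefault(line.casefold(), line)
    return table


_LEXICON: Optional[dict[str, str]] = None


def gene_lexicon() -> dict[str, str]:
    global _LEXICON
    if _LEXICON is None:
        _LEXICON = _load_lexicon()
    return _LEXICON


def default_config(source_category: str = "other") -> MapConfig:
    """Built-in class table for ``plastid``, ``mitochondrial`` or ``other``."""
    tables = json.loads(_data_text("classes.json"))
    key = source_category if source_category in tables else "other"
    classes = [
        FeatureClass(
            class_id=row["id"],
            display_label=row["label"],
            color=row["color"],
            member_patterns=tuple(row.get("patterns", ())),
            member_keys=tuple(row.get("keys", ())),
            enabled=bool(row.get("enabled", True)),
        )
        for row in tables[key]
    ]
    return MapConfig(classes=classes)


# ---------------------------------------------------------------------------
# tidy-up

_TRNA_RE = re.compile(
    r"^trn(?P<amino>f?[A-Za-z])(?:[\s_\-](?P<anticodon>[ACGTUacgtu]{3}))?$",
    re.IGNORECASE,
)


def tidy_gene_name(
    raw: Optional[str], tidy_up: bool = True, max_len: int = TIDY_MAX_LEN
) -> tuple[Optional[str], bool]:
    """Normalize a gene name; returns ``(name, rejected)``.

    With ``tidy_up`` off this is the identity.  Otherwise names longer than
    ``max_len`` (after trimming quotes/whitespace) are rejected as probable
    annotation errors; surviving names get canonical locus casing from the
    shipped lexicon and tRNAs the hyphenated ``trnX-ANT`` form (one-letter
    amino acid, uppercase RNA anticodon).  Idempotent, never lengthening.
    """
    if raw is None:
        return None, False
    if not tidy_up:
        return raw, False
    name = raw.strip().strip("\"'").strip()
    name = re.sub(r"\s+", " ", name)
    if len(name) > max_len:
        return None, True
    if not name:
        return None, False

    m = _TRNA_RE.match(name)
    if m:
        amino = m.group("amino")
        amino = "fM" if amino.casefold() == "fm" else amino.upper()
        anticodon = m.group("anticodon")
        if anticodon:
            name = f"trn{amino}-{anticodon.upper().replace('T', 'U')}"
        else:
            name = f"trn{amino}"
        return name, False

    compact = re.sub(r"[\s_]+", "", name)
    canonical = gene_lexicon().get(compact.casefold())
    if canonical is not None and len(canonical) <= len(name):
        return canonical, False
    return name, False


# ---------------------------------------------------------------------------
# classification

_KEY_CLASS = {
    "tRNA": "trna",
    "rRNA": "rrna",
    "D-loop": "dloop",
    "prim_transcript": "operon",
    "operon": "operon",
    "intron": "intron",
    "rep_origin": "origin_of_replication",
}

#: Keys treated as structural annotation (not drawn on their own) unless an
#: XML configuration maps them to a class explicitly.
_STRUCTURAL_KEYS = {"CDS", "mRNA", "exon", "misc_feature", "STS", "gap", "variation"}
_NEVER_DRAWN_KEYS = {"source", "repeat_region", "misc_difference"}


def _resolve_class_id(
    feature: FeatureInstance, config: MapConfig, name: Optional[str]
) -> str:
    if name and name in config.gene_classes:
        cid = config.gene_classes[name]
        if config.class_by_id(cid):
            return cid
    if name:
        folded = name.casefold()
        for cls in config.classes:
            if any(fnmatch.fnmatchcase(folded, p.casefold()) for p in cls.member_patterns):
                return cls.class_id
    if feature.key in config.key_classes:
        cid = config.key_classes[feature.key]
        if config.class_by_id(cid):
            return cid
    for cls in config.classes:
        if feature.key in cls.member_keys:
            return cls.class_id
    cid = _KEY_CLASS.get(feature.key)
    if cid and config.class_by_id(cid):
        return cid
    return "other" if config.class_by_id("other") else config.classes[-1].class_id


def classify_feature(
    feature: FeatureInstance,
    config: MapConfig,
    has_intron: bool = False,
) -> ClassifiedFeature:
    """Assign one feature to exactly one class and resolve its label.

    Class choice: per-gene override, then first gene-name pattern match in
    config order, then feature-key rules, then the catch-all class.  When
    intron labelling is in asterisk style, intron-containing genes get a
    ``*`` suffix on the label.
    """
    name, rejected = tidy_gene_name(
        feature.gene_name, config.tidy_up, config.tidy_max_len
    )
    if rejected:
        logger.warning("gene name %r rejected by tidy-up", feature.gene_name)
    class_id = _resolve_class_id(feature, config, name)
    cls = config.class_by_id(class_id)

    if not has_intron:
        loc = feature.location
        has_intron = len(loc.parts) >= 2 and not loc.wraps_origin

    display = name or config.gene_products.get(name or "", "") or feature.product or ""
    if name and name in config.gene_products:
        display = config.gene_products[name]
    if not display and feature.key not in ("gene",):
        display = feature.key
    if has_intron and config.intron_style == "asterisk" and display:
        display = display + "*"

    suppressed = (
        rejected
        or (cls is not None and not cls.enabled)
        or feature.key in _NEVER_DRAWN_KEYS
        or (feature.key in _STRUCTURAL_KEYS and feature.key not in config.key_classes)
        or (
            config.enabled_genes is not None
            and name is not None
            and name.rstrip("*") not in config.enabled_genes
        )
    )
    loc = feature.location
    exon_parts = (
        loc.parts
        if has_intron and len(loc.parts) >= 2 and not loc.wraps_origin
        else None
    )
    return ClassifiedFeature(
        feature=feature,
        class_id=class_id,
        display_name=display,
        gene_id=name,
        has_intron=has_intron,
        suppressed=suppressed,
        exon_parts=exon_parts,
    )


def classify_features(
    record: GenomeRecord, config: MapConfig
) -> list[ClassifiedFeature]:
    """Classify every feature of a record, with record-level context.

    Context used: a gene ``has_intron`` when its own location has >= 2
    non-wrapping parts, when a CDS/tRNA/rRNA of the same gene does, or when
    an ``intron`` feature lies within its extent.  Structural duplicates
    (a CDS/tRNA/rRNA doubling a ``gene`` feature of the same name) are
    suppressed so each locus is drawn once.
    """
    L = record.length_bp
    intron_extents = [
        f.location.extent(L)[:2] for f in record.features if f.key == "intron"
    ]
    multiexon_parts: dict[str, tuple[tuple[int, int], ...]] = {}
    for f in record.features:
        if (
            f.gene_name
            and f.key in ("CDS", "tRNA", "rRNA", "exon")
            and len(f.location.parts) >= 2
            and not f.location.wraps_origin
        ):
            multiexon_parts.setdefault(f.gene_name, f.location.parts)
    multiexon_genes = set(multiexon_parts)
    gene_names_seen: set[str] = set()
    out: list[ClassifiedFeature] = []
    for feat in record.features:
        has_intron = bool(feat.gene_name and feat.gene_name in multiexon_genes)
        if not has_intron and feat.key in ("gene", "CDS", "tRNA", "rRNA"):
            lo, hi, _ = feat.location.extent(L)
            if not feat.location.wraps_origin:
                has_intron = any(lo <= a and b <= hi for a, b in intron_extents)
        cf = classify_feature(feat, config, has_intron=has_intron)
        if cf.has_intron:
            if len(feat.location.parts) >= 2 and not feat.location.wraps_origin:
                cf.exon_parts = feat.location.parts
            elif feat.gene_name in multiexon_parts:
                cf.exon_parts = multiexon_parts[feat.gene_name]
        if (
            not cf.suppressed
            and feat.gene_name
            and feat.key in ("CDS", "tRNA", "rRNA", "mRNA")
            and feat.gene_name in gene_names_seen
        ):
            cf.suppressed = True  # structural duplicate of its gene feature
        if not cf.suppressed and feat.gene_name and feat.key in (
            "gene",
            "CDS",
            "tRNA",
            "rRNA",
        ):
            gene_names_seen.add(feat.gene_name)
        out.append(cf)
    return out


# ---------------------------------------------------------------------------
# XML configuration

_ALLOWED_ATTRS = {
    "class": {"id", "color", "label", "enabled"},
    "gene": {"name", "color", "product", "class"},
    "featurekey": {"key", "class"},
}


def _check_color(value: str, path: str) -> str:
    if not _HEX_COLOR.match(value):
        raise ConfigError(f"{path}: color {value!r} is not #RRGGBB")
    return value


def load_xml_config(stream: Union[str, IO], base: MapConfig) -> MapConfig:
    """Overlay an XML configuration file on ``base`` and return the result.

    Supported elements (see ``data/ogconfig.xsd``): ``class`` overrides or
    adds a feature class; ``gene`` sets a per-gene color, product label, or
    class; ``featurekey`` makes an extra GenBank key (e.g. ``misc_feature``)
    drawable under a class.  Anything not mentioned inherits from ``base``.
    """
    try:
        tree = etree.parse(stream) if hasattr(stream, "read") else etree.parse(str(stream))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise ConfigError(f"XML configuration could not be parsed: {exc}") from exc
    root = tree.getroot()
    if root.tag != "ogconfig":
        raise ConfigError(f"/{root.tag}: document element must be 'ogconfig'")

    cfg = base.copy()
    for i, elem in enumerate(root):
        path = f"/ogconfig/{elem.tag}[{i + 1}]"
        if elem.tag is etree.Comment:
            continue
        allowed = _ALLOWED_ATTRS.get(elem.tag)
        if allowed is None:
            raise ConfigError(f"{path}: unknown element {elem.tag!r}")
        unknown = set(elem.attrib) - allowed
        if unknown:
            raise ConfigError(f"{path}: unknown attribute(s) {sorted(unknown)}")

        if elem.tag == "class":
            cid = elem.get("id")
            if not cid:
                raise ConfigError(f"{path}: 'id' is required")
            cls = cfg.class_by_id(cid)
            if cls is None:
                color = elem.get("color")
                if color is None:
                    raise ConfigError(f"{path}: new class {cid!r} needs a color")
                cfg.classes.append(
                    FeatureClass(
                        class_id=cid,
                        display_label=elem.get("label", cid),
                        color=_check_color(color, path),
                        enabled=elem.get("enabled", "true").lower() != "false",
                    )
                )
            else:
                if elem.get("color"):
                    cls.color = _check_color(elem.get("color"), path)
                if elem.get("label"):
                    cls.display_label = elem.get("label")
                if elem.get("enabled") is not None:
                    cls.enabled = elem.get("enabled").lower() != "false"
        elif elem.tag == "gene":
            name = elem.get("name")
            if not name:
                raise ConfigError(f"{path}: 'name' is required")
            if elem.get("color"):
                cfg.gene_colors[name] = _check_color(elem.get("color"), path)
            if elem.get("product"):
                cfg.gene_products[name] = elem.get("product")
            if elem.get("class"):
                cfg.gene_classes[name] = elem.get("class")
        elif elem.tag == "featurekey":
            key = elem.get("key")
            cid = elem.get("class")
            if not key or not cid:
                raise ConfigError(f"{path}: 'key' and 'class' are required")
            cfg.key_classes[key] = cid
    return cfg
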