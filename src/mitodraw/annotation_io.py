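"""Reading and writing mitochondrial genome annotations.

Five dialects are supported: GenBank flatfile feature tables, GFF3, GTF,
6-column BED (the tabular export of annotation services such as MITOS), and
a simple TSV dialect of our own.  All parsers converge on the same internal
model (:class:`~mitodraw.model.GenomeAnnotation`): 0-based starts with
explicit lengths, a feature that spans the origin stored as one record with
``start + length > genome_length``.

Coordinate conventions per dialect:

========  =======================  =============================
dialect   file coordinates         origin-spanning representation
========  =======================  =============================
GenBank   1-based inclusive        ``join(a..L,1..b)``
GFF3      1-based inclusive        ``end > genome length`` (GFF3 circular-genome rule)
GTF       1-based inclusive        ``end > genome length``
BED       0-based half-open        ``end > genome length``
TSV       1-based inclusive        ``end > genome length``
========  =======================  =============================

The TSV dialect: UTF-8, an optional ``#length=<bp>`` directive line (and
``#topology=linear`` for the rare linear molecule), then the header
``name<TAB>type<TAB>start<TAB>end<TAB>strand``, then one row per feature
with strand ``+``/``-`` and a free-text type column fed to
:func:`classify_feature`.
"""

from __future__ import annotations

import re
from enum import Enum
from io import StringIO
from pathlib import Path
from typing import List, Optional, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

from .errors import (
    EmptyAnnotation,
    FeatureOutOfBounds,
    MalformedRecord,
    UnrecognizedFormat,
)
from .model import Feature, FeatureClass, GenomeAnnotation, Strand, Topology


class Format(str, Enum):
    genbank = "genbank"
    gff3 = "gff3"
    gtf = "gtf"
    bed = "bed"
    tsv = "tsv"


TSV_HEADER = "name\ttype\tstart\tend\tstrand"

_SUFFIX_FORMATS = {
    ".gb": Format.genbank,
    ".gbk": Format.genbank,
    ".genbank": Format.genbank,
    ".gff": Format.gff3,
    ".gff3": Format.gff3,
    ".gtf": Format.gtf,
    ".bed": Format.bed,
    ".tsv": Format.tsv,
}


# ---------------------------------------------------------------------------
# feature classification
# ---------------------------------------------------------------------------

#: canonical animal mitochondrial protein-coding genes
PCG_NAMES = frozenset(
    {
        "nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6",
        "cox1", "cox2", "cox3", "cob", "atp6", "atp8",
    }
)

_PCG_SYNONYMS = {
    "nd1": "nad1", "nd2": "nad2", "nd3": "nad3", "nd4": "nad4",
    "nd4l": "nad4l", "nd5": "nad5", "nd6": "nad6",
    "coi": "cox1", "coii": "cox2", "coiii": "cox3",
    "co1": "cox1", "co2": "cox2", "co3": "cox3",
    "coxi": "cox1", "coxii": "cox2", "coxiii": "cox3",
    "cytb": "cob", "cyb": "cob",
    "atpase6": "atp6", "atpase8": "atp8",
}

# source keys that decide the class outright, before any name rule
_SOURCE_KEY_CLASSES = {
    "trna": FeatureClass.tRNA,
    "rrna": FeatureClass.rRNA,
    "cds": FeatureClass.PCG,
    "pcg": FeatureClass.PCG,
    "other": FeatureClass.other,
}


def _normalize_gene_name(name: str) -> str:
    s = name.strip().lower()
    if s.startswith("mt-"):
        s = s[3:]
    s = re.sub(r"[^a-z0-9]", "", s)
    return _PCG_SYNONYMS.get(s, s)


def classify_feature(name: str, source_key: Optional[str] = None) -> FeatureClass:
    """Assign a feature class from its source-file key and its name.

    The cascade is deterministic: an unambiguous source key (``tRNA``,
    ``rRNA``, ``CDS``) wins; otherwise case-insensitive name rules fire
    (``trn``/``tRNA-`` prefixes, ``rrn``/``12S``/``16S``/``rRNA`` markers,
    membership in the canonical 13-gene protein-coding set with its common
    synonyms); anything left is ``other``.
    """
    if not name:
        raise ValueError("feature name is empty")
    if source_key:
        forced = _SOURCE_KEY_CLASSES.get(source_key.strip().lower())
        if forced is not None:
            return forced
    low = name.strip().lower()
    if low.startswith("trn") or low.startswith("trna-"):
        return FeatureClass.tRNA
    if low.startswith("rrn") or re.search(r"12s|16s|rrna", low):
        return FeatureClass.rRNA
    if _normalize_gene_name(name) in PCG_NAMES:
        return FeatureClass.PCG
    return FeatureClass.other


# ---------------------------------------------------------------------------
# format detection
# ---------------------------------------------------------------------------

_GTF_ATTR_RE = re.compile(r'\S+\s+"[^"]*"\s*;?')
_BED_STRANDS = {"+", "-", "."}


def detect_format(raw_text: str) -> Format:
    """Identify which of the five dialects *raw_text* is written in.

    Detection relies on structural markers only: the GenBank LOCUS/FEATURES
    skeleton, the ``##gff-version 3`` pragma, the TSV header line, GTF's
    ``key "value";`` attribute style versus GFF3's ``key=value``, and BED's
    six tab-separated columns with numeric coordinates.
    """
    if not raw_text or not raw_text.strip():
        raise UnrecognizedFormat("input is empty")
    lines = raw_text.splitlines()
    if any(l.startswith("LOCUS") for l in lines) and any(
        l.startswith("FEATURES") for l in lines
    ):
        return Format.genbank
    if lines[0].strip().startswith("##gff-version 3"):
        return Format.gff3
    for line in lines:
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if stripped.rstrip() == TSV_HEADER or line.rstrip("\n") == TSV_HEADER:
            return Format.tsv
        cols = line.rstrip("\n").split("\t")
        if len(cols) == 9:
            if _GTF_ATTR_RE.search(cols[8]):
                return Format.gtf
            if "=" in cols[8]:
                return Format.gff3
        if (
            len(cols) == 6
            and cols[1].isdigit()
            and cols[2].isdigit()
            and cols[5] in _BED_STRANDS
        ):
            return Format.bed
        break
    raise UnrecognizedFormat("no structural marker of a supported dialect matched")


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

_GENBANK_KEEP = {"gene", "CDS", "tRNA", "rRNA", "D-loop", "misc_feature"}
_NAME_QUALIFIERS = ("gene", "product", "note")


def _span_from_location(location, genome_length: int) -> Tuple[int, int]:
    """Convert a Biopython location to (0-based start, length).

    An origin-spanning ``join(a..L,1..b)`` collapses to one wrapping span;
    any other compound location collapses to its envelope.
    """
    parts = location.parts
    if len(parts) == 1:
        start, end = int(parts[0].start), int(parts[0].end)
        if start < 0 or start >= genome_length or end > genome_length:
            raise FeatureOutOfBounds(
                f"span {start + 1}..{end} exceeds genome length {genome_length}"
            )
        return start, end - start
    first_start = int(parts[0].start)
    last_start = int(parts[-1].start)
    if first_start > last_start:  # wraps the origin
        start = first_start
        tail = int(parts[-1].end)
        if start >= genome_length or tail > genome_length:
            raise FeatureOutOfBounds(
                f"wrapping span exceeds genome length {genome_length}"
            )
        length = (genome_length - start) + tail
    else:
        start = min(int(p.start) for p in parts)
        end = max(int(p.end) for p in parts)
        if end > genome_length:
            raise FeatureOutOfBounds(
                f"span {start + 1}..{end} exceeds genome length {genome_length}"
            )
        length = end - start
    if length > genome_length:
        raise FeatureOutOfBounds("feature longer than the genome")
    return start, length


def parse_genbank(raw_text: str) -> GenomeAnnotation:
    """Parse a GenBank flatfile feature table.

    Only the feature table is used; ORIGIN sequence blocks are ignored.
    Genome length and topology come from the LOCUS line.  A CDS (or tRNA or
    rRNA) sharing coordinates with its enclosing ``gene`` record collapses
    to one feature, the gene record supplying the name.
    """
    try:
        record = SeqIO.read(StringIO(raw_text), "genbank")
    except Exception as exc:
        raise MalformedRecord(f"not a parseable GenBank record: {exc}") from exc
    genome_length = len(record)
    if genome_length < 1:
        raise MalformedRecord("LOCUS line carries no sequence length")
    topology = (
        Topology.circular
        if record.annotations.get("topology") == "circular"
        else Topology.linear
    )

    # collect raw entries in file order
    entries: List[dict] = []
    for sf in record.features:
        if sf.type not in _GENBANK_KEEP:
            continue
        start, length = _span_from_location(sf.location, genome_length)
        strand = Strand.reverse if sf.location.strand == -1 else Strand.forward
        name = ""
        for qual in _NAME_QUALIFIERS:
            values = sf.qualifiers.get(qual)
            if values and str(values[0]).strip():
                name = str(values[0]).strip()
                break
        entries.append(
            {
                "start": start,
                "length": length,
                "strand": strand,
                "type": sf.type,
                "name": name,
            }
        )

    # collapse gene/CDS (or gene/tRNA, gene/rRNA) pairs at identical coordinates
    merged: dict = {}
    order: List[tuple] = []
    for e in entries:
        key = (e["start"], e["length"], e["strand"])
        if key not in merged:
            merged[key] = e
            order.append(key)
            continue
        kept = merged[key]
        if kept["type"] == "gene" and e["type"] != "gene":
            e = dict(e, name=kept["name"] or e["name"])
            merged[key] = e
        elif e["type"] == "gene" and kept["type"] != "gene":
            kept["name"] = e["name"] or kept["name"]

    features = []
    for k, key in enumerate(order, start=1):
        e = merged[key]
        name = e["name"] or f"feature_{k}"
        features.append(
            Feature(
                name=name,
                feature_class=classify_feature(name, e["type"]),
                start=e["start"],
                length=e["length"],
                strand=e["strand"],
                source_key=e["type"],
            )
        )
    title = record.description.strip().rstrip(".") if record.description else record.name
    return GenomeAnnotation(
        genome_length=genome_length,
        topology=topology,
        features=tuple(features),
        title=title or "",
    )


# ---------------------------------------------------------------------------
# tabular dialects
# ---------------------------------------------------------------------------

def _parse_int(value: str, what: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise MalformedRecord(f"non-integer {what}: {value!r}")


def _directive_length(line: str) -> Optional[int]:
    stripped = line.strip()
    if stripped.startswith("##sequence-region"):
        parts = stripped.split()
        if len(parts) >= 4:
            return _parse_int(parts[3], "sequence-region end")
    if stripped.startswith("#length="):
        return _parse_int(stripped.split("=", 1)[1], "length directive")
    return None


def _gff_like_rows(lines: List[str], fmt: Format) -> List[dict]:
    rows = []
    for line in lines:
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) != 9:
            raise MalformedRecord(
                f"{fmt.value} line has {len(cols)} columns, expected 9: {line!r}"
            )
        try:
            gf = feature_from_line(line)
        except Exception as exc:
            raise MalformedRecord(f"unparseable {fmt.value} line: {line!r}") from exc
        attrs = gf.attributes
        if fmt is Format.gff3:
            name_keys = ("Name", "gene", "product")
        else:
            name_keys = ("gene_name", "gene_id")
        name = ""
        for key in name_keys:
            values = attrs.get(key)
            if values and str(values[0]).strip():
                name = str(values[0]).strip()
                break
        start1 = _parse_int(cols[3], "start")
        end1 = _parse_int(cols[4], "end")
        rows.append(
            {
                "name": name,
                "source_key": gf.featuretype,
                "start": start1 - 1,
                "length": end1 - start1 + 1,
                "strand": Strand.reverse if gf.strand == "-" else Strand.forward,
            }
        )
    return rows


def _bed_rows(lines: List[str]) -> List[dict]:
    rows = []
    for line in lines:
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) != 6:
            raise MalformedRecord(
                f"BED line has {len(cols)} columns, expected 6: {line!r}"
            )
        start0 = _parse_int(cols[1], "chromStart")
        end0 = _parse_int(cols[2], "chromEnd")
        name = cols[3].strip()
        rows.append(
            {
                "name": "" if name in ("", ".") else name,
                "source_key": None,
                "start": start0,
                "length": end0 - start0,
                "strand": Strand.reverse if cols[5] == "-" else Strand.forward,
            }
        )
    return rows


def _tsv_rows(lines: List[str]) -> List[dict]:
    header_seen = False
    rows = []
    for line in lines:
        if not line.strip() or line.startswith("#"):
            continue
        if not header_seen:
            if line.rstrip("\n").rstrip() != TSV_HEADER:
                raise MalformedRecord(
                    "TSV input must begin with the header "
                    f"{TSV_HEADER!r}, got {line!r}"
                )
            header_seen = True
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) != 5:
            raise MalformedRecord(
                f"TSV line has {len(cols)} columns, expected 5: {line!r}"
            )
        start1 = _parse_int(cols[2], "start")
        end1 = _parse_int(cols[3], "end")
        rows.append(
            {
                "name": cols[0].strip(),
                "source_key": cols[1].strip() or None,
                "start": start1 - 1,
                "length": end1 - start1 + 1,
                "strand": Strand.reverse if cols[4].strip() == "-" else Strand.forward,
            }
        )
    if not header_seen:
        raise MalformedRecord("TSV input has no header line")
    return rows


def parse_tabular(raw_text: str, fmt) -> GenomeAnnotation:
    """Parse one of the tabular dialects (GFF3, GTF, BED, TSV).

    The genome length comes from a ``##sequence-region`` (GFF3) or
    ``#length=`` directive when present, otherwise from the maximum feature
    end; topology defaults to circular (``#topology=linear`` overrides).
    Features whose end exceeds a declared genome length wrap the origin.
    """
    fmt = Format(fmt)
    if fmt is Format.genbank:
        raise ValueError("use parse_genbank for GenBank input")
    lines = raw_text.splitlines()

    declared_length: Optional[int] = None
    topology = Topology.circular
    for line in lines:
        length = _directive_length(line)
        if length is not None and declared_length is None:
            declared_length = length
        if line.strip().lower() == "#topology=linear":
            topology = Topology.linear

    if fmt in (Format.gff3, Format.gtf):
        rows = _gff_like_rows(lines, fmt)
    elif fmt is Format.bed:
        rows = _bed_rows(lines)
    else:
        rows = _tsv_rows(lines)

    # zero feature rows are an error unless a length directive still defines
    # a (legitimately empty) genome
    if not rows and declared_length is None:
        raise EmptyAnnotation(f"no feature lines found in {fmt.value} input")

    genome_length = declared_length
    if genome_length is None:
        genome_length = max(r["start"] + r["length"] for r in rows)

    features = []
    for k, row in enumerate(rows, start=1):
        name = row["name"] or f"feature_{k}"
        start, length = row["start"], row["length"]
        if start < 0 or start >= genome_length or length < 1 or length > genome_length:
            raise FeatureOutOfBounds(
                f"{name}: span (start={start}, length={length}) does not fit "
                f"genome length {genome_length}"
            )
        features.append(
            Feature(
                name=name,
                feature_class=classify_feature(name, row["source_key"]),
                start=start,
                length=length,
                strand=row["strand"],
                source_key=row["source_key"],
            )
        )
    return GenomeAnnotation(
        genome_length=genome_length,
        topology=topology,
        features=tuple(features),
    )


def parse_text(raw_text: str, fmt=None) -> GenomeAnnotation:
    """Parse annotation text, autodetecting the dialect unless *fmt* is given."""
    fmt = Format(fmt) if fmt is not None else detect_format(raw_text)
    if fmt is Format.genbank:
        return parse_genbank(raw_text)
    return parse_tabular(raw_text, fmt)


def read_annotation(path, fmt=None) -> GenomeAnnotation:
    """Read an annotation file, autodetecting the dialect unless *fmt* is given."""
    return parse_text(Path(path).read_text(encoding="utf-8"), fmt)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_CLASS_TO_GFF_TYPE = {
    FeatureClass.PCG: "CDS",
    FeatureClass.tRNA: "tRNA",
    FeatureClass.rRNA: "rRNA",
    FeatureClass.other: "misc_feature",
}

_GENBANK_TYPES = {"CDS", "tRNA", "rRNA", "D-loop", "misc_feature", "gene"}


def _escape_gff3_value(value: str) -> str:
    return (
        value.replace("%", "%25")
        .replace(";", "%3B")
        .replace("=", "%3D")
        .replace("&", "%26")
        .replace(",", "%2C")
    )


def _feature_type(feature: Feature) -> str:
    if feature.source_key:
        return re.sub(r"\s+", "_", feature.source_key)
    return _CLASS_TO_GFF_TYPE[feature.feature_class]


def write_tsv(annotation: GenomeAnnotation) -> str:
    """Serialize to the TSV dialect.

    The type column holds the feature class, so
    ``parse_tabular(write_tsv(a), "tsv")`` reproduces names, classes,
    coordinates, and strands exactly for any valid annotation.
    """
    lines = [f"#length={annotation.genome_length}"]
    if annotation.topology is Topology.linear:
        lines.append("#topology=linear")
    lines.append(TSV_HEADER)
    for f in annotation.features:
        lines.append(
            f"{f.name}\t{f.feature_class.value}\t{f.start + 1}\t{f.end}\t{f.strand.value}"
        )
    return "\n".join(lines) + "\n"


def write_bed(annotation: GenomeAnnotation) -> str:
    """Serialize to 6-column BED (0-based half-open, MITOS-style)."""
    lines = [f"#length={annotation.genome_length}"]
    for f in annotation.features:
        lines.append(f"chrM\t{f.start}\t{f.end}\t{f.name}\t0\t{f.strand.value}")
    return "\n".join(lines) + "\n"


def write_gff3(annotation: GenomeAnnotation) -> str:
    """Serialize to GFF3; wrapping features use the circular-genome rule
    (end beyond the sequence-region length)."""
    lines = [
        "##gff-version 3",
        f"##sequence-region chrM 1 {annotation.genome_length}",
    ]
    for f in annotation.features:
        lines.append(
            "\t".join(
                [
                    "chrM",
                    "mitodraw",
                    _feature_type(f),
                    str(f.start + 1),
                    str(f.end),
                    ".",
                    f.strand.value,
                    ".",
                    f"Name={_escape_gff3_value(f.name)}",
                ]
            )
        )
    return "\n".join(lines) + "\n"


def write_gtf(annotation: GenomeAnnotation) -> str:
    """Serialize to GTF with gene_id/gene_name attributes."""
    lines = [f"#length={annotation.genome_length}"]
    for f in annotation.features:
        name = f.name.replace('"', "'")
        lines.append(
            "\t".join(
                [
                    "chrM",
                    "mitodraw",
                    _feature_type(f),
                    str(f.start + 1),
                    str(f.end),
                    ".",
                    f.strand.value,
                    ".",
                    f'gene_id "{name}"; gene_name "{name}";',
                ]
            )
        )
    return "\n".join(lines) + "\n"


def write_genbank(annotation: GenomeAnnotation) -> str:
    """Serialize to a GenBank flatfile (feature table only, no sequence)."""
    record = SeqRecord(
        Seq(None, length=annotation.genome_length),
        id="chrM",
        name="chrM",
        description=annotation.title or "mitochondrial genome annotation",
    )
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = annotation.topology.value
    L = annotation.genome_length
    for f in annotation.features:
        strand = -1 if f.strand is Strand.reverse else 1
        if f.wraps(L):
            location = CompoundLocation(
                [
                    SimpleLocation(f.start, L, strand),
                    SimpleLocation(0, f.end - L, strand),
                ]
            )
        else:
            location = SimpleLocation(f.start, f.end, strand)
        gb_type = _feature_type(f)
        if gb_type not in _GENBANK_TYPES:
            gb_type = _CLASS_TO_GFF_TYPE[f.feature_class]
        record.features.append(
            SeqFeature(location, type=gb_type, qualifiers={"gene": [f.name]})
        )
    out = StringIO()
    SeqIO.write(record, out, "genbank")
    return out.getvalue()


_WRITERS = {
    Format.genbank: write_genbank,
    Format.gff3: write_gff3,
    Format.gtf: write_gtf,
    Format.bed: write_bed,
    Format.tsv: write_tsv,
}


def write_annotation(annotation: GenomeAnnotation, path, fmt=None) -> None:
    """Write *annotation* to *path*, inferring the dialect from the suffix."""
    path = Path(path)
    if fmt is None:
        try:
            fmt = _SUFFIX_FORMATS[path.suffix.lower()]
        except KeyError:
            raise ValueError(f"cannot infer annotation format from suffix {path.suffix!r}")
    path.write_text(_WRITERS[Format(fmt)](annotation), encoding="utf-8")
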