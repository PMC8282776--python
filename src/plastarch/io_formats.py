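"""Readers and writers for the formats the pipeline touches.

A single coordinate convention is used internally: 0-based half-open
intervals on the forward strand of the record. GFF3 and GenBank flat
files are 1-based inclusive; conversion happens only here, at the
parse/serialise boundary.

Features that span the origin of a circular molecule are kept as one
annotation whose (single) interval runs past the sequence end
(``end > len``) with ``wraps_origin=True``; membership queries must go
through circular-aware helpers rather than naive range checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import SeqIO

from ._seq import DNA_ALPHABET

log = logging.getLogger(__name__)

ALIGNMENT_ALPHABET = frozenset("ACGTN-")
FEATURE_CLASSES = ("CDS", "tRNA", "rRNA", "intron", "other")

# GenBank/GFF3 feature types that are containers or metadata, not gene
# features in their own right; silently skipped rather than warned about.
_CONTAINER_TYPES = {"source", "gene", "region", "chromosome", "misc_feature",
                    "repeat_region", "exon", "mRNA"}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class GeneAnnotation:
    """One gene feature: possibly multi-part (joins), possibly origin-wrapping."""

    gene: str
    feature_class: str  # one of FEATURE_CLASSES
    strand: str  # "+" or "-"
    parts: list[tuple[int, int]]  # 0-based half-open, ordered along the strand
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if not self.parts:
            raise FormatError(f"annotation {self.gene!r} has no parts")
        if self.feature_class not in FEATURE_CLASSES:
            raise FormatError(f"unknown feature class {self.feature_class!r}")
        if self.strand not in "+-":
            raise FormatError(f"bad strand {self.strand!r}")
        for s, e in self.parts:
            if e <= s:
                raise FormatError(
                    f"annotation {self.gene!r}: empty/inverted interval [{s},{e})")

    @property
    def span(self) -> tuple[int, int]:
        """Overall [start, end) covering all parts (end may exceed the
        record length for origin-wrapping features)."""
        return min(s for s, _ in self.parts), max(e for _, e in self.parts)

    def covers(self, pos: int, length: int) -> bool:
        """Circular-aware membership test for a position in [0, length)."""
        for s, e in self.parts:
            if s <= pos < e or s <= pos + length < e:
                return True
        return False


@dataclass
class GenomeRecord:
    """A DNA molecule (circular or linear) plus its gene annotations."""

    id: str
    sequence: str
    circular: bool = False
    annotations: list[GeneAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"record {self.id!r}: characters outside A/C/G/T/N: "
                f"{sorted(bad)!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MultipleAlignment:
    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise FormatError("alignment needs at least 2 rows")
        if len(set(self.taxa)) != len(self.taxa):
            raise FormatError("duplicate taxon ids in alignment")
        n = len(self.rows[0])
        for taxon, row in zip(self.taxa, self.rows):
            if len(row) != n:
                raise FormatError(
                    f"ragged alignment: record {taxon!r} has length "
                    f"{len(row)}, expected {n}")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_taxa(self) -> int:
        return len(self.rows)


# ---------------------------------------------------------------------------
# coordinate conversion (the only place 1-based inclusive appears)

def to_zero_based(start_1based: int, end_inclusive: int) -> tuple[int, int]:
    return start_1based - 1, end_inclusive


def to_one_based(start: int, end: int) -> tuple[int, int]:
    return start + 1, end


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read FASTA into GenomeRecords (uppercased, alphabet-checked).

    A record is flagged circular when its header contains the token
    ``circular`` (case-insensitive).
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - DNA_ALPHABET
        if bad:
            ch = sorted(bad)[0]
            raise FormatError(
                f"{path}: record {rec.id!r} contains invalid character "
                f"{ch!r} at line {_find_line(path, ch)}")
        circular = "circular" in rec.description.lower().split()
        records.append(GenomeRecord(id=rec.id, sequence=seq, circular=circular))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def _find_line(path: str | Path, ch: str) -> int:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.startswith(">") and ch in line.upper():
                return i
    return -1


def write_fasta(records: Iterable[GenomeRecord], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            tag = " circular" if rec.circular else ""
            fh.write(f">{rec.id}{tag}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# annotations (GFF3 / GenBank)

def _classify(feature_type: str) -> str:
    if feature_type in ("CDS", "tRNA", "rRNA", "intron"):
        return feature_type
    log.warning("unknown feature type %r classed as 'other'", feature_type)
    return "other"


def read_annotations(path: str | Path, dialect: str) -> list[GeneAnnotation]:
    """Read gene annotations from GFF3 or a GenBank flat file.

    Coordinates are converted to 0-based half-open. Multi-part features
    (GFF3 same-ID lines, GenBank joins) become one GeneAnnotation with
    ordered parts; GenBank features spanning the origin of a circular
    record get ``wraps_origin=True`` with an unwrapped end > length.
    """
    if dialect == "gff3":
        return _read_gff3(path)
    if dialect == "genbank":
        return _read_genbank(path)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def _read_gff3(path: str | Path) -> list[GeneAnnotation]:
    from gffutils.iterators import DataIterator

    grouped: dict[str, GeneAnnotation] = {}
    out: list[GeneAnnotation] = []
    for feat in DataIterator(str(path)):
        ftype = feat.featuretype
        if ftype in _CONTAINER_TYPES:
            continue
        start, end = to_zero_based(feat.start, feat.end)
        if end <= start:
            raise FormatError(
                f"{path}: feature {feat.id or ftype} has end <= start "
                f"after conversion ([{start},{end}))")
        gene = (feat.attributes.get("gene") or feat.attributes.get("Name")
                or feat.attributes.get("ID") or [ftype])[0]
        strand = feat.strand if feat.strand in "+-" else "+"
        key = feat.attributes.get("ID", [None])[0]
        if key is not None and key in grouped:
            ann = grouped[key]
            ann.parts.append((start, end))
            ann.parts.sort()
            continue
        ann = GeneAnnotation(gene=gene, feature_class=_classify(ftype),
                             strand=strand, parts=[(start, end)])
        if key is not None:
            grouped[key] = ann
        out.append(ann)
    return out


def _read_genbank(path: str | Path) -> list[GeneAnnotation]:
    out: list[GeneAnnotation] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        length = len(rec.seq)
        for feat in rec.features:
            if feat.type in _CONTAINER_TYPES:
                continue
            # Biopython locations are already 0-based half-open
            parts = [(int(p.start), int(p.end)) for p in feat.location.parts]
            for s, e in parts:
                if e <= s:
                    raise FormatError(
                        f"{path}: feature in {rec.id} has end <= start")
            strand = "-" if feat.location.strand == -1 else "+"
            wraps = False
            # origin wrap shows up as a join whose last forward part starts
            # at 0 while an earlier part ends at the sequence end
            if len(parts) >= 2:
                ordered = parts if strand == "+" else parts[::-1]
                if ordered[0][1] == length and ordered[-1][0] == 0:
                    head, tail = ordered[0], ordered[-1]
                    parts = [(head[0], length + tail[1])]
                    wraps = True
            gene = (feat.qualifiers.get("gene")
                    or feat.qualifiers.get("locus_tag") or [feat.type])[0]
            out.append(GeneAnnotation(
                gene=gene, feature_class=_classify(feat.type),
                strand=strand, parts=sorted(parts), wraps_origin=wraps))
    return out


def write_gff3(annotations: Sequence[GeneAnnotation], record_id: str,
               record_length: int, path: str | Path) -> None:
    """Emit annotations as GFF3 (1-based inclusive, multi-part via shared ID)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {record_id} 1 {record_length}\n")
        for i, ann in enumerate(annotations):
            fid = f"feat{i}"
            for s, e in ann.parts:
                # unwrap origin-spanning parts back onto the circle
                if e > record_length:
                    segs = [(s, record_length), (0, e - record_length)]
                else:
                    segs = [(s, e)]
                for ss, ee in segs:
                    o_s, o_e = to_one_based(ss, ee)
                    fh.write("\t".join([
                        record_id, "plastarch", ann.feature_class,
                        str(o_s), str(o_e), ".", ann.strand, ".",
                        f"ID={fid};gene={ann.gene}"]) + "\n")


# ---------------------------------------------------------------------------
# alignments

def read_alignment(path: str | Path) -> MultipleAlignment:
    taxa, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxa.append(rec.id)
        row = str(rec.seq).upper()
        bad = set(row) - ALIGNMENT_ALPHABET
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} contains invalid character "
                f"{sorted(bad)[0]!r}")
        rows.append(row)
    if len(rows) < 2:
        raise FormatError(f"{path}: alignment needs >= 2 records")
    n = len(rows[0])
    for taxon, row in zip(taxa, rows):
        if len(row) != n:
            raise FormatError(
                f"{path}: ragged alignment, record {taxon!r} has length "
                f"{len(row)} but {taxa[0]!r} has {n}")
    return MultipleAlignment(taxa=taxa, rows=rows)


def write_alignment(aln: MultipleAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for taxon, row in zip(aln.taxa, aln.rows):
            fh.write(f">{taxon}\n{row}\n")


# ---------------------------------------------------------------------------
# trees

def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a rooted/unrooted newick tree; node supports and branch lengths
    are retained on the dendropy tree but unused by the analyses here."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"{path}: newick parse error: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {x for x in labels if labels.count(x) > 1}
    if dupes:
        raise FormatError(f"{path}: duplicate leaf labels {sorted(dupes)!r}")
    return tree


# ---------------------------------------------------------------------------
# tables

def write_table(rows: Sequence[dict], path: str | Path,
                columns: Sequence[str] | None = None) -> None:
    """Write mappings as a TSV with a header row.

    Column order is declaration order of the first row (or the explicit
    ``columns``); all rows must share one key set.
    """
    if columns is None:
        if not rows:
            raise ValueError("zero rows and no declared header")
        columns = list(rows[0].keys())
    colset = set(columns)
    for i, row in enumerate(rows):
        if set(row.keys()) != colset:
            raise ValueError(
                f"row {i} keys {sorted(row)!r} do not match header "
                f"{sorted(colset)!r}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in columns) + "\n")


def read_table(path: str | Path) -> list[dict]:
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty table")
    header = lines[0].split("\t")
    return [dict(zip(header, line.split("\t"))) for line in lines[1:]]
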