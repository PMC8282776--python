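"""Inverted-repeat detection and quadripartite plastome architecture.

The plastome of most land plants is a circle of four regions,
LSC–IRb–SSC–IRa, where IRa is the exact reverse complement of IRb and
the two single-copy regions (large and small) lie between the repeat
arms. This module:

* finds the IR pair as the maximal pair of disjoint, mutually
  reverse-complementary intervals on the circle (seed 31-mers shared
  between the sequence and its reverse complement, exact extension,
  circularity handled by scanning the doubled sequence and normalising
  back to [0, len));
* canonically rotates the circle so the LSC starts at position 0 and
  reports the four region lengths (IR length is one copy, so
  LSC + SSC + 2·IR = total);
* calls the gene at (or flanking) each of the four junctions
  JLB (LSC/IRb), JSB (IRb/SSC), JSA (SSC/IRa), JLA (IRa/LSC);
* classifies boundary shifts between two junction reports and counts
  gene inventories.

N policy: N matches nothing (including N), so assembly gaps truncate IR
extension; a partition is still attempted from the longest clean pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from ._seq import complement, revcomp
from .io_formats import GeneAnnotation, GenomeRecord

log = logging.getLogger(__name__)

ANCHOR_K = 31
JUNCTIONS = ("JLB", "JSB", "JSA", "JLA")

_CLASS_PRIORITY = {"CDS": 0, "rRNA": 1, "tRNA": 2, "intron": 3, "other": 3}


class ArchitectureError(ValueError):
    """Raised when a genome lacks the expected quadripartite structure."""


@dataclass
class QuadripartitePartition:
    """LSC/IRb/SSC/IRa coordinates on the canonical rotation."""

    rotation_offset: int  # bp subtracted (mod total) to reach the canonical rotation
    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]

    @property
    def lsc_len(self) -> int:
        return self.lsc[1] - self.lsc[0]

    @property
    def ssc_len(self) -> int:
        return self.ssc[1] - self.ssc[0]

    @property
    def ir_len(self) -> int:
        return self.irb[1] - self.irb[0]

    @property
    def total_len(self) -> int:
        return self.ira[1]

    @property
    def junctions(self) -> dict[str, int]:
        """Junction positions on the canonical rotation (JLA == total, i.e.
        position 0 on the circle), strictly increasing."""
        return {"JLB": self.lsc[1], "JSB": self.irb[1],
                "JSA": self.ssc[1], "JLA": self.ira[1]}


@dataclass
class JunctionEntry:
    junction: str
    position: int
    status: str  # "gene_spans" | "intergenic"
    gene: Optional[str]  # gene symbol, or "geneA–geneB" flanking pair, or None
    left_bp: Optional[int]  # overhang (gene_spans) or distance (intergenic)
    right_bp: Optional[int]

    @property
    def context(self) -> Optional[str]:
        """The gene context string compared by classify_boundary_shift."""
        return self.gene


@dataclass
class JunctionReport:
    entries: dict[str, JunctionEntry]

    def __post_init__(self) -> None:
        if set(self.entries) != set(JUNCTIONS):
            raise ValueError("junction report must cover exactly JLB/JSB/JSA/JLA")

    def __getitem__(self, junction: str) -> JunctionEntry:
        return self.entries[junction]


@dataclass
class BoundaryShift:
    junction: str
    reference_context: Optional[str]
    observed_context: Optional[str]
    shifted: bool


@dataclass
class GeneInventory:
    cds_total: int = 0
    cds_unique: int = 0
    rrna_total: int = 0
    rrna_unique: int = 0
    trna_total: int = 0
    trna_unique: int = 0


# ---------------------------------------------------------------------------
# IR detection


def _extend_pair(seq: str, L: int, a0: int, a1: int, b0: int, b1: int,
                 circular: bool, budget: int) -> tuple[int, int, int, int]:
    """Extend an anchored inverted match.

    Arms are inclusive integer ranges [a0, a1] and [b0, b1] on the
    (possibly doubled) circle, paired so seq[a0+t] == comp(seq[b1-t]).
    Extension stops when bases mismatch (N never matches), the mismatch
    budget is spent, or the arms would meet on the circle.
    """

    def ch(i: int) -> str:
        return seq[i % L] if circular else (seq[i] if 0 <= i < L else "\0")

    def matches(x: str, y: str) -> bool:
        return x != "N" and x != "\0" and y != "\0" and x == complement(y)

    # grow outward: a0 left, b1 right (these two positions pair up)
    pending = 0
    while True:
        na0, nb1 = a0 - 1, b1 + 1
        if circular:
            gap = (na0 - nb1 - 1) % L  # bases strictly between b1 and a0 on the circle
            if (a1 - na0 + 1) + (nb1 - b0 + 1) > L or gap < 0:
                break
            if (na0 - b1 - 1) % L == 0 or (nb1 % L) == (na0 % L):
                break
        else:
            if na0 < 0 or nb1 >= L:
                break
        if matches(ch(na0), ch(nb1)):
            a0, b1 = na0, nb1
            pending = 0
        elif budget > 0 and ch(na0) != "\0" and ch(nb1) != "\0" \
                and ch(na0) != "N" and ch(nb1) != "N":
            budget -= 1
            pending += 1
            a0, b1 = na0, nb1
        else:
            break
        if circular and ((b1 - a0 + 1) >= L or (b1 % L) == ((a0 - 1) % L)):
            break
    a0 += pending
    b1 -= pending
    # grow inward ends: a1 right, b0 left (these pair up); arms must stay disjoint
    pending = 0
    while True:
        na1, nb0 = a1 + 1, b0 - 1
        if na1 >= nb0:  # arms touching/overlapping in doubled coordinates
            break
        if circular:
            if (na1 % L) == (nb0 % L):
                break
        else:
            if na1 >= L or nb0 < 0:
                break
        if matches(ch(na1), ch(nb0)):
            a1, b0 = na1, nb0
            pending = 0
        elif budget > 0 and ch(na1) != "\0" and ch(nb0) != "\0" \
                and ch(na1) != "N" and ch(nb0) != "N":
            budget -= 1
            pending += 1
            a1, b0 = na1, nb0
        else:
            break
    a1 -= pending
    b0 += pending
    return a0, a1, b0, b1


def detect_inverted_repeat(genome: GenomeRecord, min_len: int = 1000,
                           max_mismatches: int = 0,
                           ) -> Optional[tuple[tuple[int, int], tuple[int, int]]]:
    """Find the maximal pair of disjoint mutually reverse-complementary
    intervals of length >= min_len.

    Returns the two intervals ordered by start, as 0-based half-open
    coordinates on [0, len); an interval whose end exceeds len wraps the
    origin. Returns None when no qualifying pair exists. Ties between
    equally long pairs break toward the pair whose smaller start
    coordinate is smallest.
    """
    seq = genome.sequence
    L = len(seq)
    if L < 2 * min_len:
        raise ArchitectureError(
            f"genome length {L} < 2*min_len ({2 * min_len})")
    if not genome.circular:
        log.warning("record %s is linear; IR search without origin wrap",
                    genome.id)
    k = min(ANCHOR_K, min_len)
    circular = genome.circular
    doubled = seq + seq[:k - 1] if circular else seq
    n_starts = L if circular else L - k + 1

    kmer_pos: dict[str, list[int]] = {}
    for i in range(n_starts):
        kmer = doubled[i:i + k]
        if "N" in kmer:
            continue
        kmer_pos.setdefault(kmer, []).append(i)

    found: list[tuple[int, int, int, int]] = []  # inclusive arm coords, a-first

    def already_covered(i: int, j: int) -> bool:
        # anchor arms are seq[i:i+k] and seq[j:j+k]; the pairing constant is
        # i + (j + k - 1) along any extension of the same repeat
        d = (i + j + k - 1) % L if circular else i + j + k - 1
        for a0, a1, b0, b1 in found:
            df = (a0 + b1) % L if circular else a0 + b1
            if df != d:
                continue
            if circular:
                if (i - a0) % L <= (a1 - a0) and (j - b0) % L <= (b1 - b0):
                    return True
            else:
                if a0 <= i and i + k - 1 <= a1 and b0 <= j and j + k - 1 <= b1:
                    return True
        return False

    for j in range(n_starts):
        kmer = doubled[j:j + k]
        if "N" in kmer:
            continue
        for i in kmer_pos.get(revcomp(kmer), ()):
            if i >= j:  # each unordered pair once; skip self-anchors
                continue
            if circular and (j - (i + k - 1)) % L == 0:
                continue
            if already_covered(i, j):
                continue
            a0, a1, b0, b1 = _extend_pair(seq, L, i, i + k - 1, j, j + k - 1,
                                          circular, max_mismatches)
            if a1 - a0 + 1 >= k:
                found.append((a0, a1, b0, b1))

    best = None
    for a0, a1, b0, b1 in found:
        length = a1 - a0 + 1
        if length < min_len:
            continue
        arm_a = (a0 % L, a0 % L + length)
        arm_b = (b0 % L, b0 % L + length)
        pair = tuple(sorted([arm_a, arm_b]))
        key = (-length, pair[0][0], pair[1][0])
        if best is None or key < best[0]:
            best = (key, pair)
    return best[1] if best else None


# ---------------------------------------------------------------------------
# quadripartite partition


def partition_quadripartite(genome: GenomeRecord, min_len: int = 1000,
                            max_mismatches: int = 0) -> QuadripartitePartition:
    """Partition a circular plastome into LSC/IRb/SSC/IRa.

    The two single-copy regions between the IR arms are identified on
    the circle; the longer is the LSC. The canonical rotation puts the
    LSC start at position 0, followed by IRb, SSC, IRa.
    """
    pair = detect_inverted_repeat(genome, min_len=min_len,
                                  max_mismatches=max_mismatches)
    if pair is None:
        raise ArchitectureError(f"{genome.id}: no quadripartite structure")
    L = len(genome.sequence)
    (s1, e1), (s2, e2) = pair
    ir_len = e1 - s1
    gap_after_1 = (s2 - e1) % L  # single-copy region between arm1 end and arm2 start
    gap_after_2 = (s1 - e2) % L
    if gap_after_1 == gap_after_2:
        log.warning("%s: single-copy regions equal in length; tie broken "
                    "toward the region preceding the smaller IR start",
                    genome.id)
        # LSC is the region that precedes the lexicographically smaller IR start
        lsc_start, irb_start = e2 % L, s1
        ssc_start = e1 % L
    elif gap_after_1 > gap_after_2:
        # LSC lies after arm1; canonical order: LSC, arm2 (=IRb), SSC, arm1 (=IRa)
        lsc_start, irb_start = e1 % L, s2
        ssc_start = e2 % L
    else:
        lsc_start, irb_start = e2 % L, s1
        ssc_start = e1 % L
    lsc_len = (irb_start - lsc_start) % L
    ssc_len = L - lsc_len - 2 * ir_len
    offset = lsc_start
    part = QuadripartitePartition(
        rotation_offset=offset,
        lsc=(0, lsc_len),
        irb=(lsc_len, lsc_len + ir_len),
        ssc=(lsc_len + ir_len, lsc_len + ir_len + ssc_len),
        ira=(lsc_len + ir_len + ssc_len, L))
    assert part.lsc_len + part.ssc_len + 2 * part.ir_len == L
    assert (ssc_start - offset) % L == part.ssc[0]
    return part


def rotate_record(genome: GenomeRecord,
                  partition: QuadripartitePartition) -> GenomeRecord:
    """Return the genome on the canonical rotation with annotations remapped."""
    L = len(genome.sequence)
    off = partition.rotation_offset
    seq = genome.sequence[off:] + genome.sequence[:off]
    anns = [remap_annotation(a, off, L) for a in genome.annotations]
    return GenomeRecord(id=genome.id, sequence=seq, circular=genome.circular,
                        annotations=anns)


def remap_annotation(ann: GeneAnnotation, offset: int, length: int) -> GeneAnnotation:
    """Shift an annotation by -offset on a circle of the given length."""
    parts = []
    wraps = False
    for s, e in ann.parts:
        ns = (s - offset) % length
        ne = ns + (e - s)
        if ne > length:
            wraps = True
        parts.append((ns, ne))
    parts.sort()
    return GeneAnnotation(gene=ann.gene, feature_class=ann.feature_class,
                          strand=ann.strand, parts=parts, wraps_origin=wraps)


# ---------------------------------------------------------------------------
# junction report


def _gene_span_on_circle(ann: GeneAnnotation, L: int) -> tuple[int, int]:
    s, e = ann.span
    return s, e


def _spans_junction(ann: GeneAnnotation, pos: int, L: int) -> bool:
    """True when the gene's overall span strictly contains the junction
    point (covers the bases on both sides), circular-aware."""
    s, e = _gene_span_on_circle(ann, L)
    for p in (pos, pos + L):
        if s < p < e:
            return True
    return False


def junction_report(partition: QuadripartitePartition,
                    annotations: Sequence[GeneAnnotation]) -> JunctionReport:
    """Call the gene at (or flanking) each of the four junctions.

    Annotations must already be on the canonical rotation. When several
    genes span one junction the winner has feature-class priority
    CDS > rRNA > tRNA > other, then the larger total overlap. With no
    spanning gene, the nearest gene on each side is reported as
    "geneA–geneB" with distances; with no annotations at all, distances
    are unavailable (None).
    """
    L = partition.total_len
    entries = {}
    for junction, pos in partition.junctions.items():
        spanning = [a for a in annotations if _spans_junction(a, pos, L)]
        if spanning:
            def rank(a: GeneAnnotation):
                s, e = a.span
                p = pos if s < pos < e else pos + L
                overlap = min(e, p + (e - s)) - max(s, p - (e - s))  # span length proxy
                return (_CLASS_PRIORITY.get(a.feature_class, 3), -(e - s))
            best = sorted(spanning, key=rank)[0]
            s, e = best.span
            p = pos if s < pos < e else pos + L
            entries[junction] = JunctionEntry(
                junction=junction, position=pos, status="gene_spans",
                gene=best.gene, left_bp=p - s, right_bp=e - p)
            continue
        if not annotations:
            entries[junction] = JunctionEntry(
                junction=junction, position=pos, status="intergenic",
                gene=None, left_bp=None, right_bp=None)
            continue
        # nearest gene ending before the junction / starting after it
        def left_dist(a: GeneAnnotation) -> int:
            return (pos - a.span[1]) % L

        def right_dist(a: GeneAnnotation) -> int:
            return (a.span[0] - pos) % L

        left = min(annotations, key=left_dist)
        right = min(annotations, key=right_dist)
        entries[junction] = JunctionEntry(
            junction=junction, position=pos, status="intergenic",
            gene=f"{left.gene}–{right.gene}",
            left_bp=left_dist(left), right_bp=right_dist(right))
    return JunctionReport(entries=entries)


def classify_boundary_shift(observed: JunctionReport,
                            reference: JunctionReport) -> list[BoundaryShift]:
    """One BoundaryShift per junction; shifted iff the gene context differs."""
    out = []
    for junction in JUNCTIONS:
        ref = reference[junction].context
        obs = observed[junction].context
        out.append(BoundaryShift(junction=junction, reference_context=ref,
                                 observed_context=obs, shifted=ref != obs))
    return out


# ---------------------------------------------------------------------------
# gene inventory


def gene_inventory(annotations: Sequence[GeneAnnotation]) -> GeneInventory:
    """Count CDS/rRNA/tRNA features: totals count every occurrence
    (IR-duplicated genes count twice), uniques count distinct symbols."""
    inv = GeneInventory()
    seen: dict[str, set[str]] = {"CDS": set(), "rRNA": set(), "tRNA": set()}
    for ann in annotations:
        if ann.feature_class not in seen:
            continue
        seen[ann.feature_class].add(ann.gene)
        if ann.feature_class == "CDS":
            inv.cds_total += 1
        elif ann.feature_class == "rRNA":
            inv.rrna_total += 1
        else:
            inv.trna_total += 1
    inv.cds_unique = len(seen["CDS"])
    inv.rrna_unique = len(seen["rRNA"])
    inv.trna_unique = len(seen["tRNA"])
    return inv
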