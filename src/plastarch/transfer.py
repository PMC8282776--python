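"""Quantify plastome-derived DNA in a mitogenome by fragment tiling.

The procedure cuts the plastome into k-bp fragments (k = 30 by default,
non-overlapping) and maps each fragment against both strands of the
mitogenome. Two denominations are reported: the fraction of fragments
that map anywhere, and the merged mitogenome coverage of all hit
intervals as a percentage of mitogenome length — the latter is the
headline number. Exact matching is the default (a deterministic lower
bound on true transfer); a small mismatch tolerance is available via
pigeonhole seeding. N never matches anything.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from ._seq import revcomp
from .io_formats import GenomeRecord


@dataclass
class Fragment:
    index: int
    start: int  # on the linearised source genome
    seq: str
    contains_n: bool


@dataclass
class Hit:
    fragment_index: int
    target_start: int
    target_end: int
    strand: str  # "+" or "-"


@dataclass
class TransferReport:
    k: int
    step: int
    max_mismatches: int
    n_fragments: int
    n_mapped: int
    fragment_fraction: float  # percent of fragments with >= 1 hit
    mito_bases_covered: int   # merged union of hit intervals
    mito_len: int
    mito_percent: float       # 100 * mito_bases_covered / mito_len


def tile_genome(genome: GenomeRecord, k: int = 30,
                step: int = 30) -> list[Fragment]:
    """Cut the linearised sequence into k-bp fragments, step apart.

    A trailing fragment shorter than k is dropped. Fragments containing
    N are emitted but flagged (they can never map).
    """
    if k < 1 or step < 1:
        raise ValueError("k and step must be >= 1")
    seq = genome.sequence
    if k > len(seq):
        raise ValueError(f"k={k} exceeds genome length {len(seq)}")
    frags = []
    for idx, start in enumerate(range(0, len(seq) - k + 1, step)):
        sub = seq[start:start + k]
        frags.append(Fragment(index=idx, start=start, seq=sub,
                              contains_n="N" in sub))
    return frags


def _exact_index(target: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(target) - k + 1):
        kmer = target[i:i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return index


def _seed_index(target: str, seed_len: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(target) - seed_len + 1):
        index.setdefault(target[i:i + seed_len], []).append(i)
    return index


def _hamming_ok(a: str, b: str, budget: int) -> bool:
    mism = 0
    for x, y in zip(a, b):
        if x == "N" or y == "N":
            return False
        if x != y:
            mism += 1
            if mism > budget:
                return False
    return True


def map_fragments(fragments: Sequence[Fragment], target: GenomeRecord,
                  max_mismatches: int = 0) -> list[Hit]:
    """All occurrences of each fragment in the target, both strands.

    Hits are reported in target coordinates; a reverse-strand hit means
    the fragment equals the reverse complement of the target interval.
    Mismatch tolerance uses pigeonhole seeding (one of max_mismatches+1
    equal slices must match exactly) with full Hamming verification.
    """
    if not target.sequence:
        raise ValueError("empty target")
    if not fragments:
        return []
    tgt = target.sequence
    k = len(fragments[0].seq)
    if any(len(f.seq) != k for f in fragments):
        raise ValueError("fragments must share one length")
    hits: list[Hit] = []
    if max_mismatches == 0:
        index = _exact_index(tgt, k)
        for frag in fragments:
            if frag.contains_n:
                continue
            for pos in index.get(frag.seq, ()):
                hits.append(Hit(frag.index, pos, pos + k, "+"))
            rc = revcomp(frag.seq)
            for pos in index.get(rc, ()):
                hits.append(Hit(frag.index, pos, pos + k, "-"))
        return hits
    n_seeds = max_mismatches + 1
    seed_len = k // n_seeds
    if seed_len < 4:
        raise ValueError("k too small for this mismatch tolerance")
    index = _seed_index(tgt, seed_len)
    for frag in fragments:
        if frag.contains_n:
            continue
        for query, strand in ((frag.seq, "+"), (revcomp(frag.seq), "-")):
            candidates = set()
            for s in range(n_seeds):
                off = s * seed_len
                for pos in index.get(query[off:off + seed_len], ()):
                    start = pos - off
                    if 0 <= start <= len(tgt) - k:
                        candidates.add(start)
            for start in sorted(candidates):
                if _hamming_ok(query, tgt[start:start + k], max_mismatches):
                    hits.append(Hit(frag.index, start, start + k, strand))
    return hits


def merged_coverage(intervals: Sequence[tuple[int, int]]) -> int:
    """Total bases in the union of half-open intervals."""
    if not intervals:
        return 0
    merged = 0
    cur_s, cur_e = None, None
    for s, e in sorted(intervals):
        if cur_s is None:
            cur_s, cur_e = s, e
        elif s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            merged += cur_e - cur_s
            cur_s, cur_e = s, e
    merged += cur_e - cur_s
    return merged


def quantify_transfer(plastome: GenomeRecord, mitogenome: GenomeRecord,
                      k: int = 30, step: int = 30,
                      max_mismatches: int = 0) -> TransferReport:
    """Tile the plastome and measure how much of the mitogenome it explains."""
    frags = tile_genome(plastome, k=k, step=step)
    hits = map_fragments(frags, mitogenome, max_mismatches=max_mismatches)
    mapped = {h.fragment_index for h in hits}
    covered = merged_coverage([(h.target_start, h.target_end) for h in hits])
    mito_len = len(mitogenome.sequence)
    return TransferReport(
        k=k, step=step, max_mismatches=max_mismatches,
        n_fragments=len(frags), n_mapped=len(mapped),
        fragment_fraction=100.0 * len(mapped) / len(frags),
        mito_bases_covered=covered, mito_len=mito_len,
        mito_percent=100.0 * covered / mito_len)


def hits_to_bed(hits: Sequence[Hit], chrom: str) -> str:
    """Render hits as BED lines (0-based half-open, strand in column 6)."""
    lines = [f"{chrom}\t{h.target_start}\t{h.target_end}\t"
             f"frag{h.fragment_index}\t0\t{h.strand}" for h in hits]
    return "\n".join(lines) + ("\n" if lines else "")
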