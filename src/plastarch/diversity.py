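"""Nucleotide diversity, GC profiling, and amino-acid tandem repeats.

Nucleotide diversity is Nei's per-site π with pairwise deletion: the
mean over sequence pairs of d_ij / L_ij, where L_ij counts alignment
columns in which both rows carry an unambiguous base (no gap, no N) and
d_ij counts those columns where the bases differ. With complete data
this is Σ_{i<j} (d_ij/L) / C(n,2); pairs with L_ij = 0 are dropped from
the average (and n_pairs_used reports how many pairs contributed); a window
in which *every* pair has L_ij = 0 has no defined diversity and is
signalled as such rather than reported as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np

from ._seq import encode
from .io_formats import GenomeRecord, MultipleAlignment


class UndefinedDiversityError(ValueError):
    """Every sequence pair had zero valid (ungapped, non-N) sites."""


@dataclass
class PiWindow:
    start: int
    end: int
    midpoint: int
    n_pairs_used: int
    pi: float  # NaN when undefined for this window


@dataclass
class PiProfile:
    window: int
    step: int
    windows: list[PiWindow]


@dataclass
class RepeatHit:
    sequence_id: str
    unit: str
    copies: int
    start: int  # residue index

    @property
    def end(self) -> int:
        return self.start + self.copies * len(self.unit)


# ---------------------------------------------------------------------------
# pi


def _pi_core(mat: np.ndarray) -> tuple[float, int]:
    """(pi, n_pairs_used) for an encoded alignment slice; pi is NaN when no
    pair has valid sites."""
    n = mat.shape[0]
    valid = mat != 255
    total = 0.0
    used = 0
    for i, j in combinations(range(n), 2):
        both = valid[i] & valid[j]
        L_ij = int(both.sum())
        if L_ij == 0:
            continue
        d_ij = int((mat[i][both] != mat[j][both]).sum())
        total += d_ij / L_ij
        used += 1
    if used == 0:
        return math.nan, 0
    return total / used, used


def nucleotide_diversity(alignment: MultipleAlignment,
                         columns: Optional[tuple[int, int]] = None) -> float:
    """Nei's per-site π over a column interval (default: whole alignment)."""
    start, end = columns if columns is not None else (0, alignment.length)
    if not (0 <= start < end <= alignment.length):
        raise ValueError(f"interval [{start},{end}) outside the alignment")
    mat = np.stack([encode(row)[start:end] for row in alignment.rows])
    pi, used = _pi_core(mat)
    if used == 0:
        raise UndefinedDiversityError(
            f"no pair has valid sites in columns [{start},{end})")
    return pi


def sliding_pi(alignment: MultipleAlignment, window: int = 600,
               step: int = 200) -> PiProfile:
    """π in sliding windows: full windows only, starting at column 0.

    Windows where diversity is undefined (all pairs gap/N-only) carry
    pi = NaN with n_pairs_used = 0.
    """
    if window > alignment.length:
        raise ValueError(
            f"window {window} exceeds alignment length {alignment.length}")
    if step < 1:
        raise ValueError("step must be >= 1")
    mat = np.stack([encode(row) for row in alignment.rows])
    out = []
    for start in range(0, alignment.length - window + 1, step):
        end = start + window
        pi, used = _pi_core(mat[:, start:end])
        out.append(PiWindow(start=start, end=end, midpoint=(start + end) // 2,
                            n_pairs_used=used, pi=pi))
    return PiProfile(window=window, step=step, windows=out)


# ---------------------------------------------------------------------------
# GC profile


def gc_profile(genome: GenomeRecord, window: int,
               step: int) -> list[tuple[int, float]]:
    """(midpoint, GC fraction) per window; GC = (G+C)/(non-N bases).

    Circular genomes wrap, so every window is full; linear genomes emit
    full windows only. All-N windows yield NaN.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    seq = genome.sequence
    L = len(seq)
    src = seq + seq[:window - 1] if genome.circular else seq
    n_starts = L if genome.circular else L - window + 1
    out = []
    for start in range(0, n_starts, step):
        win = src[start:start + window]
        denom = window - win.count("N")
        gc = (win.count("G") + win.count("C")) / denom if denom else math.nan
        out.append(((start + window // 2) % L, gc))
    return out


# ---------------------------------------------------------------------------
# amino-acid tandem repeats

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")


def aa_repeat_scan(protein: str, min_unit: int = 1, max_unit: int = 10,
                   min_total_len: int = 10,
                   sequence_id: str = "protein") -> list[RepeatHit]:
    """Maximal perfect tandem repeats with unit length in [min_unit, max_unit].

    A hit is a maximal run of ≥2 full copies of a repeat unit whose
    covered span (copies × unit length) is at least min_total_len.
    Overlapping hits are collapsed to the maximal one per locus (larger
    span wins, then smaller unit, then smaller start).
    """
    bad = set(protein) - AA_ALPHABET
    if bad:
        raise ValueError(f"invalid amino-acid characters {sorted(bad)!r}")
    n = len(protein)
    raw: list[RepeatHit] = []
    for u in range(min_unit, max_unit + 1):
        if 2 * u > n:
            break
        # eq[j] is True when protein[j] == protein[j-u]; a maximal True run
        # over j in [a, b] is the tandem region protein[a-u : b+1]
        j = u
        while j < n:
            if protein[j] != protein[j - u]:
                j += 1
                continue
            a = j
            while j < n and protein[j] == protein[j - u]:
                j += 1
            b = j - 1
            region_start = a - u
            region_len = (b - a + 1) + u
            copies = region_len // u
            if copies >= 2 and copies * u >= min_total_len:
                unit = protein[region_start:region_start + u]
                # a region whose unit is itself periodic is already reported
                # at the smaller unit length
                if not _is_periodic(unit):
                    raw.append(RepeatHit(sequence_id=sequence_id, unit=unit,
                                         copies=copies, start=region_start))
    raw.sort(key=lambda h: (-h.copies * len(h.unit), len(h.unit), h.start))
    kept: list[RepeatHit] = []
    for hit in raw:
        if all(hit.end <= k.start or k.end <= hit.start for k in kept):
            kept.append(hit)
    kept.sort(key=lambda h: h.start)
    return kept


def _is_periodic(unit: str) -> bool:
    """True when the unit is an exact repetition of a shorter unit."""
    u = len(unit)
    for p in range(1, u):
        if u % p == 0 and unit == unit[:p] * (u // p):
            return True
    return False
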