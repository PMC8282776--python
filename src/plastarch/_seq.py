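"""Low-level DNA string helpers shared across the package.

Everything here operates on uppercase DNA strings over {A,C,G,T,N}.
N is an assembly-gap placeholder: it complements to N but never *matches*
anything in repeat/fragment comparisons (that policy lives in the callers).
"""

from __future__ import annotations

import numpy as np

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# numeric encoding used by the vectorised diversity/oracle code
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode A,C,G,T as 0..3 and anything else (N, gaps) as 255."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])
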