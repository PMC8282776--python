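"""Synthetic organelle genomes, alignments and trees with exact ground truth.

The generators emulate the architectures the analyses are built for:

* plastomes with the quadripartite LSC–IRb–SSC–IRa layout, either
  "hoya_like" (a hugely expanded IR flanking a very short SSC, with
  *rpl22* at the IR–LSC junction and *ndhF* spanning the IR–SSC
  junction) or "outgroup_like" (a conventional ~26 kb IR and long SSC
  with *ycf1* spanning the IR–SSC junction);
* mitogenomes with planted plastome-derived segments at known positions;
* alignments with controlled per-site polymorphism;
* rooted trees with a labelled ingroup clade carrying a binary
  architecture character, optionally with planted homoplasy.

Everything is seeded and byte-deterministic, and every generator returns
the ground truth needed to score the corresponding analysis stage
exactly.

A construction detail that matters for scoring: the planted IR pair is
made *maximal* — the four bases flanking the junctions are adjusted so
that no single-base extension preserves the reverse-complement relation.
Without this, a ~1/4-per-junction chance background match would let the
detector legitimately report an IR one base wider than planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._seq import complement, random_dna, revcomp
from .io_formats import GeneAnnotation, GenomeRecord

# Architecture presets (full scale, bp), after the study system:
# ingroup plastomes have IR ~41.7 kb and SSC ~2.3 kb; outgroups have a
# conventional IR ~26 kb and SSC ~18 kb. LSC ~91 kb in both.
HOYA_LIKE_FULL = dict(lsc_len=91_000, irb_len=41_700, ssc_len=2_300)
OUTGROUP_LIKE_FULL = dict(lsc_len=91_000, irb_len=26_000, ssc_len=18_000)
DEFAULT_TEST_SCALE = 0.1  # 1/10-scale presets keep test suites fast


@dataclass
class PlastomeSpec:
    lsc_len: int
    irb_len: int
    ssc_len: int
    gene_layout: str = "hoya_like"  # hoya_like | outgroup_like | custom
    junction_overhangs: dict = field(default_factory=dict)  # junction -> bp into the IR
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lsc_len, self.irb_len, self.ssc_len) < 1:
            raise ValueError("all region lengths must be >= 1")
        if self.gene_layout not in ("hoya_like", "outgroup_like", "custom"):
            raise ValueError(f"unknown gene_layout {self.gene_layout!r}")

    @property
    def total_len(self) -> int:
        return self.lsc_len + self.ssc_len + 2 * self.irb_len


def hoya_like_spec(scale: float = DEFAULT_TEST_SCALE, seed: int = 0) -> PlastomeSpec:
    return PlastomeSpec(**{k: int(round(v * scale)) for k, v in HOYA_LIKE_FULL.items()},
                        gene_layout="hoya_like", seed=seed)


def outgroup_like_spec(scale: float = DEFAULT_TEST_SCALE, seed: int = 0) -> PlastomeSpec:
    return PlastomeSpec(**{k: int(round(v * scale)) for k, v in OUTGROUP_LIKE_FULL.items()},
                        gene_layout="outgroup_like", seed=seed)


@dataclass
class TransferSpec:
    mito_len: int
    transfers: list[tuple[tuple[int, int], int, str]]  # (plastome interval, insertion point, strand)
    seed: int = 0


@dataclass
class GroundTruth:
    """Whatever the corresponding analysis stage needs to be scored exactly."""

    partition: Optional[dict] = None       # region name -> (start, end)
    gene_positions: Optional[dict] = None  # gene -> list of (start, end, strand)
    transfers: Optional[list] = None       # mitogenome intervals of plastome origin
    expected_pi_per_column: Optional[np.ndarray] = None
    expected_pi: Optional[float] = None
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# plastomes


def _break_extension(seq: list[str], fix_pos: int, partner_pos: int,
                     rng: np.random.Generator) -> None:
    """Redraw seq[fix_pos] so it does not complement seq[partner_pos]."""
    banned = complement(seq[partner_pos])
    choices = [b for b in "ACGT" if b != banned]
    if seq[fix_pos] == banned:
        seq[fix_pos] = choices[rng.integers(0, len(choices))]


def _enforce_ir_maximality(seq: list[str], lsc: int, ir: int, ssc: int,
                           rng: np.random.Generator) -> None:
    """Make the planted IR pair non-extendable at both junction pairs.

    Layout: LSC [0,l) | IRb [l,l+r) | SSC [l+r,l+r+s) | IRa [l+r+s,L).
    Leftward growth of IRb pairs the last LSC base with the first base of
    the genome (the base just past IRa on the circle); rightward growth
    pairs the first SSC base with the last SSC base.
    """
    l, r, s = lsc, ir, ssc
    _break_extension(seq, l - 1, 0, rng)
    _break_extension(seq, l + r, l + r + s - 1, rng)


def _place_junction_genes(spec: PlastomeSpec) -> list[GeneAnnotation]:
    l, r, s = spec.lsc_len, spec.irb_len, spec.ssc_len
    total = spec.total_len
    jlb, jsb = l, l + r

    def overhang(j: str, default: int) -> int:
        return int(spec.junction_overhangs.get(j, default))

    anns: list[GeneAnnotation] = []
    if spec.gene_layout == "custom":
        return anns

    # rpl22 at the IR–LSC junction (both layouts, as in the ingroup and
    # the Jasminanthes-style outgroup): body in the LSC, short overhang
    # into IRb.
    oh = overhang("JLB", min(60, r // 4))
    body = min(420, l // 4)
    if oh >= r or body >= l:
        raise ValueError("JLB junction gene does not fit the flanking regions")
    anns.append(GeneAnnotation("rpl22", "CDS", "-",
                               parts=[(jlb - body, jlb + oh)]))

    if spec.gene_layout == "hoya_like":
        # ndhF spans the IR–SSC junction: overhang into IRb, body in SSC.
        oh = overhang("JSB", min(90, r // 4))
        body = min(600, max(1, s - 2))
        if oh >= r or body >= s:
            raise ValueError("JSB junction gene does not fit the flanking regions")
        anns.append(GeneAnnotation("ndhF", "CDS", "-",
                                   parts=[(jsb - oh, jsb + body)]))
    else:
        # outgroup layout: ycf1 spans the IR–SSC junction with a long SSC body.
        oh = overhang("JSB", min(90, r // 4))
        body = min(1700, max(1, s - 2))
        if oh >= r or body >= s:
            raise ValueError("JSB junction gene does not fit the flanking regions")
        anns.append(GeneAnnotation("ycf1", "CDS", "+",
                                   parts=[(jsb - oh, jsb + body)]))

    # A few housekeeping genes away from junctions, plus an IR-duplicated
    # rRNA/tRNA block mirrored into IRa, so inventories and nearest-gene
    # reports have something to count.
    anns.append(GeneAnnotation("psbA", "CDS", "+",
                               parts=[(min(50, l // 10), min(50, l // 10) + min(300, l // 5))]))
    mid = l // 2
    anns.append(GeneAnnotation("rbcL", "CDS", "+",
                               parts=[(mid, mid + min(400, l // 5))]))
    ir_block = [("rrn16", "rRNA", min(150, r // 8)),
                ("rrn23", "rRNA", min(280, r // 8)),
                ("trnV-GAC", "tRNA", min(72, r // 10))]
    offset = r // 3
    for gene, cls, size in ir_block:
        b_start = l + offset
        anns.append(GeneAnnotation(gene, cls, "+", parts=[(b_start, b_start + size)]))
        # mirrored copy in IRa, opposite strand
        a_end = total - offset
        anns.append(GeneAnnotation(gene, cls, "-", parts=[(a_end - size, a_end)]))
        offset += size + max(20, r // 20)
    return anns


def make_plastome(spec: PlastomeSpec) -> tuple[GenomeRecord, GroundTruth]:
    """Emit a circular quadripartite plastome with planted junction genes.

    The sequence is random LSC ⊕ IRb ⊕ random SSC ⊕ revcomp(IRb); IRa is
    the exact reverse complement of IRb, and the pair is maximal by
    construction (see module docstring).
    """
    rng = np.random.default_rng(spec.seed)
    l, r, s = spec.lsc_len, spec.irb_len, spec.ssc_len
    lsc = random_dna(rng, l)
    irb = random_dna(rng, r)
    ssc = random_dna(rng, s)
    seq = list(lsc + irb + ssc + revcomp(irb))
    _enforce_ir_maximality(seq, l, r, s, rng)
    annotations = _place_junction_genes(spec)
    record = GenomeRecord(id=f"synthetic_plastome_seed{spec.seed}",
                          sequence="".join(seq), circular=True,
                          annotations=annotations)
    partition = {"lsc": (0, l), "irb": (l, l + r),
                 "ssc": (l + r, l + r + s), "ira": (l + r + s, spec.total_len)}
    gene_positions = {}
    for ann in annotations:
        gene_positions.setdefault(ann.gene, []).append(
            (ann.parts[0][0], ann.parts[-1][1], ann.strand))
    truth = GroundTruth(partition=partition, gene_positions=gene_positions,
                        extra={"layout": spec.gene_layout})
    return record, truth


def mutate_genome(record: GenomeRecord, subst_rate: float,
                  preserve_ir_identity: bool, seed: int,
                  partition: Optional[dict] = None) -> GenomeRecord:
    """Apply per-site substitutions, optionally keeping the IR pair intact.

    With ``preserve_ir_identity`` the partition (as produced by
    make_plastome ground truth) must be supplied: substitutions in IRb are
    mirrored into IRa, IRa is never mutated independently, and the
    junction-flanking bases are re-adjusted so the planted IR pair stays
    maximal.
    """
    if not 0 <= subst_rate < 1:
        raise ValueError("subst_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    seq = list(record.sequence)
    L = len(seq)
    if preserve_ir_identity:
        if partition is None:
            raise ValueError("preserve_ir_identity requires the partition ground truth")
        irb = partition["irb"]
        ira = partition["ira"]
        skip = set(range(ira[0], ira[1]))
    else:
        skip = set()
    hits = np.nonzero(rng.random(L) < subst_rate)[0]
    for pos in hits:
        pos = int(pos)
        if pos in skip:
            continue
        old = seq[pos]
        alts = [b for b in "ACGT" if b != old]
        new = alts[rng.integers(0, 3)]
        seq[pos] = new
        if preserve_ir_identity and irb[0] <= pos < irb[1]:
            mirror = ira[1] - 1 - (pos - irb[0])
            seq[mirror] = complement(new)
    if preserve_ir_identity:
        l = irb[0]
        r = irb[1] - irb[0]
        s = ira[0] - irb[1]
        _enforce_ir_maximality(seq, l, r, s, rng)
    return GenomeRecord(id=record.id + f"_mut{seed}", sequence="".join(seq),
                        circular=record.circular,
                        annotations=list(record.annotations))


# ---------------------------------------------------------------------------
# mitogenomes with planted transfers


def make_mitogenome(plastome: GenomeRecord,
                    spec: TransferSpec) -> tuple[GenomeRecord, GroundTruth]:
    """Random mitogenome background with plastome segments copied in.

    Each transfer overwrites the background at its insertion point, so the
    mitogenome length stays ``mito_len`` and the ground-truth intervals of
    plastome origin are exact by construction.
    """
    rng = np.random.default_rng(spec.seed)
    seq = list(random_dna(rng, spec.mito_len))
    placed: list[tuple[int, int]] = []
    for (ps, pe), at, strand in spec.transfers:
        if not (0 <= ps < pe <= len(plastome.sequence)):
            raise ValueError(f"transfer interval [{ps},{pe}) outside the plastome")
        seg = plastome.sequence[ps:pe]
        if strand == "-":
            seg = revcomp(seg)
        end = at + len(seg)
        if at < 0 or end > spec.mito_len:
            raise ValueError(f"insertion [{at},{end}) outside the mitogenome")
        for s0, e0 in placed:
            if at < e0 and s0 < end:
                raise ValueError(
                    f"overlapping insertions: [{at},{end}) vs [{s0},{e0})")
        seq[at:end] = list(seg)
        placed.append((at, end))
    placed.sort()
    record = GenomeRecord(id=f"synthetic_mitogenome_seed{spec.seed}",
                          sequence="".join(seq), circular=True)
    return record, GroundTruth(transfers=placed)


# ---------------------------------------------------------------------------
# alignments


def make_alignment(n_taxa: int, length: int, theta: float, seed: int,
                   block: Optional[tuple[int, int, float]] = None,
                   ) -> tuple["MultipleAlignment", GroundTruth]:
    """Alignment with independent columns at polymorphism probability theta.

    Each column is invariant with probability 1−theta; otherwise it
    segregates two alleles with the minor count drawn uniformly over
    1..n−1. Ground truth records per-column diversity 2p(1−p)·n/(n−1)
    for the realised splits (which for a biallelic column equals the
    exact pairwise-difference fraction). ``block=(start, end, theta2)``
    overrides theta on a column range, for planting a high-diversity
    region.
    """
    from .io_formats import MultipleAlignment

    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if not 0 <= theta <= 1:
        raise ValueError("theta must be in [0, 1]")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    mat = np.empty((n_taxa, length), dtype="<U1")
    exp_pi = np.zeros(length)
    for col in range(length):
        t = theta
        if block is not None and block[0] <= col < block[1]:
            t = block[2]
        major = bases[rng.integers(0, 4)]
        if rng.random() < t:
            k = int(rng.integers(1, n_taxa))  # minor allele count
            minor = bases[(np.flatnonzero(bases == major)[0] + rng.integers(1, 4)) % 4]
            carriers = rng.choice(n_taxa, size=k, replace=False)
            colvals = np.full(n_taxa, major, dtype="<U1")
            colvals[carriers] = minor
            mat[:, col] = colvals
            exp_pi[col] = 2 * k * (n_taxa - k) / (n_taxa * (n_taxa - 1))
        else:
            mat[:, col] = major
    rows = ["".join(mat[i]) for i in range(n_taxa)]
    aln = MultipleAlignment(taxa=[f"taxon{i}" for i in range(n_taxa)], rows=rows)
    truth = GroundTruth(expected_pi_per_column=exp_pi,
                        expected_pi=float(exp_pi.mean()))
    return aln, truth


# ---------------------------------------------------------------------------
# trees with an architecture character


def _random_clade(labels: list[str], rng: np.random.Generator) -> str:
    """Random bifurcating newick subtree over the labels."""
    nodes = list(labels)
    rng.shuffle(nodes)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return nodes[0]


def make_tree_with_character(n_ingroup: int, n_outgroup: int, seed: int,
                             mode: str = "clean", n_flips: int = 0):
    """Rooted bifurcating tree with a labelled ingroup clade and a binary
    architecture character.

    Clean mode assigns state 1 to every ingroup leaf and 0 elsewhere (the
    one-gain synapomorphy configuration). Homoplasy mode additionally
    flips ``n_flips`` ingroup leaves back to 0, and records the flipped
    leaves so tests can enumerate the true minimum change count.

    Returns (dendropy tree, states dict, info dict) where info carries
    ``ingroup`` (the leaf-label set of the ingroup clade) and
    ``flipped``.
    """
    import dendropy

    if n_ingroup < 2:
        raise ValueError("n_ingroup must be >= 2")
    if n_outgroup < 1:
        raise ValueError("n_outgroup must be >= 1")
    if mode not in ("clean", "homoplasy"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    ingroup = [f"ing{i}" for i in range(n_ingroup)]
    outgroup = [f"out{i}" for i in range(n_outgroup)]
    sub = _random_clade(ingroup, rng)
    # outgroup taxa attach as a ladder outside the ingroup clade
    for out in outgroup:
        sub = f"({sub},{out})"
    tree = dendropy.Tree.get(data=sub + ";", schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = True
    states = {t: 1 for t in ingroup}
    states.update({t: 0 for t in outgroup})
    flipped: list[str] = []
    if mode == "homoplasy":
        if n_flips < 1 or n_flips >= n_ingroup:
            raise ValueError("n_flips must be in [1, n_ingroup)")
        flipped = [ingroup[i] for i in rng.choice(n_ingroup, size=n_flips,
                                                  replace=False)]
        for t in flipped:
            states[t] = 0
    info = {"ingroup": set(ingroup), "flipped": flipped}
    return tree, states, info
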