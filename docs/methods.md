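# Methods

## The biological setting

Most land-plant plastomes are circular molecules of four regions: a
large single-copy region (LSC), a small single-copy region (SSC), and
two identical inverted-repeat copies (IRb, IRa) separating them. The
four boundary points are named after the regions they join: JLB
(LSC/IRb), JSB (IRb/SSC), JSA (SSC/IRa) and JLA (IRa/LSC). IR expansion
and contraction moves these junctions relative to the gene map, so *which
gene sits on a junction* is a compact, discrete descriptor of plastome
architecture. In the study system this package targets, ingroup
plastomes carry an IR of roughly 41.7 kb per copy and an SSC of only
~2.3 kb, with *rpl22* at the IR–LSC junction and *ndhF* spanning the
IR–SSC junction, whereas outgroup-type plastomes have a conventional
~26 kb IR and ~18 kb SSC with *ycf1* on the IR–SSC junction. The
package treats the ycf1→ndhF junction change as a discrete character
and asks, by parsimony, whether it is a synapomorphy of the ingroup.

## IR detection and partitioning

Detection takes assembled sequence only. The IR pair is defined as the
maximal pair of disjoint, mutually reverse-complementary intervals of
length ≥ `min_len` (default 1,000 bp — generous margin below any true
plastome IR, large enough to ignore small dispersed repeats). The
algorithm anchors on 31-mers shared between the sequence and its
reverse complement, extends each anchored match base-by-base in both
directions, and handles circularity by scanning the doubled sequence
and reducing coordinates mod the genome length. Anchors that fall
inside an already-extended repeat are skipped using the invariant that
the sum of paired positions is constant along one inverted match.
Maximality means no single-base extension on either end of either arm
preserves the reverse-complement relation.

Numerical/degenerate-input choices:

* **N policy.** N matches nothing, including N. Assembly gaps therefore
  truncate extension, and the longest clean pair is still reported.
* **Ties** between equally long candidate pairs break toward the pair
  whose smaller start coordinate is smallest; equal-length single-copy
  regions break toward the region preceding the smaller IR start (with
  a logged warning). Both rules exist only for determinism.
* **Mismatch tolerance** (`max_mismatches > 0`) extends greedily with a
  shared budget and trims trailing mismatches; the default, and
  everything scored here, is exact matching.
* **Linear inputs** are processed without origin wrap, with a warning.

The partition puts the longer single-copy region first (LSC ≥ SSC),
rotates the circle so the LSC starts at 0, and reports IR length per
copy, so `LSC + SSC + 2·IR = total` is an enforced invariant.
Annotations are remapped onto the canonical rotation; features crossing
the origin are kept unsplit with an end past the sequence length and a
`wraps_origin` flag, and all junction queries are circular-aware.

Junction calls prefer, among genes spanning a junction, CDS over rRNA
over tRNA over anything else, then the larger span — protein-coding
junction genes are the standard report and a deterministic rule is
needed when a tRNA overlaps the same point.

## Nucleotide diversity

π is Nei's per-site diversity under pairwise deletion: for each pair of
rows, d_ij/L_ij over the columns where both rows have an unambiguous
base; the window value is the mean over pairs with L_ij > 0, and
`n_pairs_used` records how many contributed. A window where every pair
has L_ij = 0 is *undefined* (NaN), deliberately distinct from 0.
Pairwise (rather than complete) deletion was chosen because plastome
alignments carry localized indels that would otherwise zero out long
windows. Sliding windows default to 600 columns at step 200 — common
values for plastome π profiles; they are parameters, not constants, and
full windows only are emitted. TSV output prints π to 4 decimals.

## Amino-acid tandem repeats

Junction-adjacent and highly variable plastid genes (*ycf1*, *accD*)
often carry long perfect amino-acid tandem repeats that make their
alignment unreliable. The scanner reports maximal perfect tandem runs
with unit length 1–10 and total span ≥ 10 residues, keeps only
primitive units (a poly-Q run is one unit-1 hit, not five different
descriptions of itself), and collapses overlapping reports to the
maximal hit per locus (larger span, then smaller unit, then smaller
start).

## Plastid-to-mitogenome transfer

The quantifier cuts the plastome into non-overlapping 30-bp fragments
(a partition, not a sliding window; the trailing sub-30 bp remainder is
dropped) and matches each fragment exactly against both strands of the
mitogenome. Exact matching is deterministic and yields a lower bound on
true transferred content, which matches the "at least" framing such
estimates carry; a 1–2 mismatch tolerance is available via pigeonhole
seeding. Two denominations are always reported: the fraction of
fragments with at least one hit, and the merged union of hit intervals
as a fraction of mitogenome length. The merged-coverage denomination is
the headline number because that is the arithmetic behind the published
style of statement (56,698 of 718,734 bp = 7.889%).

With exact matching and tile step = k, a planted transfer of length L
is recovered to within 2(k−1) bp — up to k−1 bases can be lost at each
edge where no complete tile fits.

## Parsimony trait mapping

Characters are unordered with equal costs — the minimal formalisation
when only presence/absence of a boundary shift is at stake. The upward
pass is Hartigan's count form: each state is scored by how many child
sets contain it; the node keeps the majority states and the change
count grows by (children − majority). On bifurcating trees this is
exactly Fitch's intersection/union rule; on polytomies the naive rule
undercounts (a star with tip states 1,1,0,0 needs two changes, not
one), so the count form is used and polytomies are handled natively
rather than arbitrarily resolved. Missing leaf states contribute the
full observed state set and never increment the count. The downward
pass fixes one most-parsimonious labelling (root takes the smallest
state in its set; a child keeps its parent's state when possible) and
records the change edges; the number of change edges equals the upward
count.

`test_synapomorphy(mapping, clade, state)` is true iff the derived
state arises on exactly one edge, that edge is the stem of the (checked
monophyletic) clade, and no change occurs inside the clade.

## The synthetic-data generator

The generator emits the study conditions at 1/10 scale by default
(full-scale generation is supported): ingroup-like plastomes of
LSC 9,100 / IR 4,170 / SSC 230 bp and outgroup-like plastomes of
LSC 9,100 / IR 2,600 / SSC 1,800 bp, scaled from the ~91 kb / 41.7 kb /
2.3 kb and ~91 kb / 26 kb / 18 kb architectures of the real system.
Sequence composition is uniform over {A,C,G,T}; IRa is constructed as
the exact reverse complement of IRb; junction genes are planted per
layout (*rpl22* across JLB in both; *ndhF* across JSB in the ingroup
layout, *ycf1* in the outgroup layout), along with a duplicated
rRNA/tRNA block inside the IR and single-copy CDSs for inventory and
nearest-gene reporting.

Two construction details make ground truth exact rather than merely
very probable:

* **Planted IRs are maximal by construction.** The four bases flanking
  the junctions are redrawn so that no single-base extension preserves
  the reverse-complement relation; otherwise a ~1/4-per-junction chance
  background match would let a correct detector legitimately report an
  IR one base wider than "planted", and exact-recovery scoring would be
  ill-posed. `mutate_genome(..., preserve_ir_identity=True)` mirrors
  every IR substitution into the other arm and re-enforces the same
  flanking property, so architecture remains exactly recoverable at the
  substitution rates used (≤ 0.02).
* **Transfers overwrite background.** Planted plastome segments replace
  mitogenome background in place, so the mitogenome length and the
  ground-truth intervals are exact. Chance 30-mer matches between
  uniform background and plastome have probability < 1e-12 at the
  scales used and are ignored.

Alignment columns are independent: invariant with probability 1−θ,
otherwise biallelic with the minor-allele count uniform on 1..n−1. For
a biallelic column the recorded "expected" π, 2p(1−p)·n/(n−1), equals
the realised pairwise-difference fraction exactly, so alignment ground
truth is exact too. Character trees are random bifurcating ingroup
clades with outgroup taxa attached as an outer ladder; clean mode gives
all ingroup leaves the derived state, homoplasy mode flips a chosen
number back.

What the generator does **not** emulate — and therefore what passing
tests do not demonstrate about real data: realistic base composition or
codon structure, substitution-rate heterogeneity (no gamma rates),
indels within genomes, gene-order rearrangements beyond the IR/SSC
junction placement, partial IR homology at the boundaries
(mismatch-tolerant IR ends in real assemblies would shorten exact IR
calls), and mitogenome repeat structure. Real plastome annotation also
carries multi-exon genes and pseudogene fragments at junctions that the
planted gene models only approximate.

## Problem sizes and scoring

The packaged acceptance run scores: exact IR-boundary recovery on 100
mutated 1/10-scale genomes (both layouts, rates 0/0.01/0.02); detector
equality with an exhaustive antidiagonal inverted-repeat search on 50
genomes under 5 kb; the partition sum invariant on every partition;
sliding-window π against a brute-force pairwise oracle (tolerance
1e-12) over 100 alignments of up to 10 rows × 2,000 columns with
injected gaps/Ns; planted-transfer recovery within 2(k−1) bp per
transfer on 100 mitogenomes plus exact self-mapping; parsimony counts
against exhaustive enumeration on 200 random trees of up to 12 leaves
(including polytomies, 3-state characters and missing data); and the
end-to-end 5-ingroup/2-outgroup synapomorphy study. These sizes keep
the whole run around a minute on one CPU while exercising every code
path the full-scale analyses use; full-size genomes run through the
same functions unchanged.

## Known limitations

* The IR detector assumes exact identity of the two IR copies (the
  biological expectation); assemblies whose IR copies differ would
  yield a shorter exact core, flagged only by disagreement with
  externally reported lengths.
* Mismatch-tolerant extension is greedy and not guaranteed maximal for
  `max_mismatches > 0`.
* π windows are column-indexed on the alignment, not genome-anchored;
  mapping windows back to one reference genome's coordinates is the
  caller's concern.
* The transfer quantifier reports sequence identity, not directionality
  of transfer; it cannot distinguish plastome→mitogenome movement from
  shared ancestry of a segment.
* `test_synapomorphy` evaluates one most-parsimonious reconstruction;
  for characters with many equally parsimonious reconstructions a
  stem-gain under one reconstruction need not hold under all. For the
  binary, near-clean characters it targets, the reconstruction is
  unique.
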