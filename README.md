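# plastarch

Analysis toolkit for plastome (chloroplast genome) architecture, built
around the question of how the quadripartite plastome is reorganised in
lineages with expanded inverted repeats: it detects the inverted-repeat
(IR) pair of a circular plastome, partitions the molecule into
LSC–IRb–SSC–IRa, calls the genes at the four region junctions,
classifies junction boundary shifts across taxa, computes sliding-window
nucleotide diversity (π) along alignments, quantifies plastome-derived
DNA in a mitogenome by 30-bp fragment tiling, and maps architecture
characters onto a phylogeny by parsimony to test for synapomorphies.
A seeded synthetic-genome generator with exact ground truth makes every
stage testable without downloading any sequence data.

The package is aimed at organelle-genome and plastome-evolution work of
the kind done for the *Hoya* group (Apocynaceae), where ingroup
plastomes carry a hugely expanded IR (~41.7 kb per copy) flanking one of
the shortest SSCs known in angiosperms (~2.3 kb), and the IR/SSC
junction gene has shifted from *ycf1* (the outgroup condition) to
*ndhF* — a shared derived state of the whole clade.

## What it computes

* **IR detection.** The IR pair is the maximal pair of disjoint,
  mutually reverse-complementary intervals on the circle, found by
  anchoring 31-mers shared between the sequence and its reverse
  complement and extending exactly (N matches nothing). Circularity is
  handled by scanning the doubled sequence and normalising coordinates
  back to `[0, len)`.
* **Quadripartite partition.** The longer single-copy region between the
  arms is the LSC; the genome is canonically rotated so the LSC starts
  at position 0, and `LSC + SSC + 2·IR = total` holds by construction.
  IR length is reported per copy.
* **Junction genes.** For each junction (JLB, JSB, JSA, JLA) the gene
  whose span contains the junction point is reported with its overhang
  into each side, or the nearest flanking genes with distances.
* **Nucleotide diversity.** Nei's per-site π with pairwise deletion of
  gaps/N: the mean over sequence pairs of d_ij/L_ij, in sliding windows
  (600/200 column defaults).
* **Plastid-to-mitogenome transfer.** The plastome is cut into 30-bp
  fragments; each is matched exactly against both strands of the
  mitogenome; the merged union of hit intervals over the mitogenome
  length is the headline percentage (the mapped-fragment fraction is
  reported alongside).
* **Trait mapping.** Fitch small parsimony (Hartigan's count-based pass,
  exact on polytomies) with a synapomorphy test: a derived state that
  arises exactly once, on the stem edge of a named clade, with no
  reversal inside it.

## Worked example

Generate a 1/10-scale ingroup-like plastome and report its architecture:

```bash
plastarch simulate --layout hoya_like --seed 1 --out-dir sim
plastarch architecture --fasta sim/plastome.fasta \
    --annotations sim/plastome.gff3 --out sim/arch.tsv
```

`sim/arch.tsv` then contains (abridged):

```
id                        total  lsc   ssc  ir    gene_at_JLB  gene_at_JSB
synthetic_plastome_seed1  17670  9100  230  4170  rpl22        ndhF
```

i.e. a 17,670 bp circle partitioned into a 9,100 bp LSC, 230 bp SSC and
two 4,170 bp IR copies (9,100 + 230 + 2×4,170 = 17,670), with *rpl22*
at the LSC/IRb junction and *ndhF* spanning the IRb/SSC junction — the
ingroup architecture at one tenth scale. An outgroup-like simulation
(`--layout outgroup_like`) instead reports a 1,800 bp SSC, 2,600 bp IR
and *ycf1* at the IR/SSC junction.

The full synthetic study — five ingroup-like and two outgroup-like
genomes, a junction-shift matrix against an outgroup reference, and a
parsimony test of the IR/SSC shift on a clean ingroup/outgroup tree:

```bash
plastarch run-all --n-ingroup 5 --n-outgroup 2 --seed 0 --out-dir study
```

prints

```json
{"n_ingroup": 5, "n_outgroup": 2, "seed": 0, "scale": 0.1,
 "jsb_min_changes": 1, "jsb_shift_synapomorphy": true}
```

meaning the IR/SSC junction-gene change maps as a single gain on the
stem of the ingroup clade — a synapomorphy.

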