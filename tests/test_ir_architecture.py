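"""IR detection, quadripartite partitioning, junction calls, inventories."""

import numpy as np
import pytest

from _oracles import brute_force_inverted_repeat
from plastarch._seq import random_dna, revcomp
from plastarch.io_formats import GeneAnnotation, GenomeRecord
from plastarch.ir_architecture import (ArchitectureError, JUNCTIONS,
                                       classify_boundary_shift,
                                       detect_inverted_repeat, gene_inventory,
                                       junction_report,
                                       partition_quadripartite,
                                       remap_annotation, rotate_record)
from plastarch.synthetic_data import (PlastomeSpec, hoya_like_spec,
                                      make_plastome, mutate_genome,
                                      outgroup_like_spec)


def _canonical_junction_genes(rec):
    part = partition_quadripartite(rec, min_len=400)
    anns = [remap_annotation(a, part.rotation_offset, len(rec.sequence))
            for a in rec.annotations]
    report = junction_report(part, anns)
    return part, report


class TestDetect:
    def test_recovers_planted_intervals(self):
        rec, truth = make_plastome(PlastomeSpec(5000, 1500, 400, seed=42))
        pair = detect_inverted_repeat(rec, min_len=1000)
        assert pair == (truth.partition["irb"], truth.partition["ira"])
        assert pair[0][1] - pair[0][0] == 1500

    def test_random_sequence_has_no_ir(self, rng):
        rec = GenomeRecord("r", random_dna(rng, 10000), circular=True)
        assert detect_inverted_repeat(rec, min_len=1000) is None

    def test_short_genome_rejected(self, rng):
        rec = GenomeRecord("r", random_dna(rng, 1200), circular=True)
        with pytest.raises(ArchitectureError):
            detect_inverted_repeat(rec, min_len=1000)

    def test_all_n_sequence(self):
        rec = GenomeRecord("n", "N" * 5000, circular=True)
        assert detect_inverted_repeat(rec, min_len=1000) is None

    def test_n_truncates_extension(self):
        # plant an IR, then punch an N into one arm: the N splits the match
        # and only the longer clean piece qualifies
        rec, truth = make_plastome(PlastomeSpec(4000, 1200, 400, seed=8))
        bs, be = truth.partition["irb"]
        seq = list(rec.sequence)
        seq[bs + 300] = "N"
        broken = GenomeRecord("n", "".join(seq), circular=True)
        pair = detect_inverted_repeat(broken, min_len=500)
        assert pair is not None
        length = pair[0][1] - pair[0][0]
        assert length == 1200 - 301  # the clean piece right of the N

    def test_linear_genome_processed_without_wrap(self):
        rec, truth = make_plastome(PlastomeSpec(4000, 1200, 400, seed=9))
        linear = GenomeRecord("lin", rec.sequence, circular=False)
        pair = detect_inverted_repeat(linear, min_len=1000)
        assert pair == (truth.partition["irb"], truth.partition["ira"])

    def test_recovery_under_mirrored_mutation(self):
        rec, truth = make_plastome(hoya_like_spec(seed=77))
        mut = mutate_genome(rec, 0.02, True, seed=78, partition=truth.partition)
        pair = detect_inverted_repeat(mut, min_len=1000)
        assert pair == (truth.partition["irb"], truth.partition["ira"])

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        if seed % 4 == 0:  # some IR-free genomes
            rec = GenomeRecord("r", random_dna(rng, 2600), circular=True)
        else:
            lsc = int(rng.integers(1200, 1800))
            ir = int(rng.integers(400, 650))
            ssc = int(rng.integers(150, 350))
            rec, _ = make_plastome(PlastomeSpec(lsc, ir, ssc, seed=seed))
        got = detect_inverted_repeat(rec, min_len=400)
        expected = brute_force_inverted_repeat(rec.sequence, min_len=400)
        assert got == expected


class TestPartition:
    def test_synthetic_lengths(self):
        rec, _ = make_plastome(PlastomeSpec(5000, 1500, 400, seed=42))
        part = partition_quadripartite(rec)
        assert (part.lsc_len, part.ssc_len, part.ir_len) == (5000, 400, 1500)
        assert part.total_len == 8400

    def test_sum_invariant(self):
        for seed in range(5):
            rec, _ = make_plastome(hoya_like_spec(seed=seed))
            p = partition_quadripartite(rec)
            assert p.lsc_len + p.ssc_len + 2 * p.ir_len == p.total_len
            assert p.lsc_len >= p.ssc_len

    def test_no_ir_raises_architecture_error(self, rng):
        rec = GenomeRecord("r", random_dna(rng, 8000), circular=True)
        with pytest.raises(ArchitectureError, match="no quadripartite"):
            partition_quadripartite(rec)

    def test_rotation_invariance(self):
        rec, _ = make_plastome(hoya_like_spec(seed=5))
        L = len(rec.sequence)
        base = partition_quadripartite(rec)
        for off in (1, 4000, 9100, 11000, 13400, L - 1):
            rot = GenomeRecord("rot", rec.sequence[off:] + rec.sequence[:off],
                               circular=True)
            p = partition_quadripartite(rot)
            assert (p.lsc_len, p.ssc_len, p.ir_len) == \
                   (base.lsc_len, base.ssc_len, base.ir_len)
            assert (p.rotation_offset + off) % L == base.rotation_offset

    def test_strand_invariance(self):
        rec, _ = make_plastome(outgroup_like_spec(seed=6))
        base = partition_quadripartite(rec)
        rc = GenomeRecord("rc", revcomp(rec.sequence), circular=True)
        p = partition_quadripartite(rc)
        assert (p.lsc_len, p.ssc_len, p.ir_len) == \
               (base.lsc_len, base.ssc_len, base.ir_len)

    def test_ira_revcomp_of_irb_on_canonical_rotation(self):
        rec, _ = make_plastome(hoya_like_spec(seed=2))
        part = partition_quadripartite(rec)
        rot = rotate_record(rec, part)
        assert rot.sequence[slice(*part.ira)] == \
            revcomp(rot.sequence[slice(*part.irb)])


class TestJunctionReport:
    def test_hoya_layout(self):
        rec, _ = make_plastome(hoya_like_spec(seed=0))
        _, report = _canonical_junction_genes(rec)
        assert report["JSB"].status == "gene_spans"
        assert report["JSB"].gene == "ndhF"
        assert report["JLB"].gene == "rpl22"

    def test_outgroup_layout(self):
        rec, _ = make_plastome(outgroup_like_spec(seed=0))
        _, report = _canonical_junction_genes(rec)
        assert report["JSB"].gene == "ycf1"

    def test_positions_strictly_increasing(self):
        rec, _ = make_plastome(hoya_like_spec(seed=3))
        _, report = _canonical_junction_genes(rec)
        positions = [report[j].position for j in JUNCTIONS]
        assert positions == sorted(positions)
        assert len(set(positions)) == 4

    def test_intergenic_flanking_pair_distances(self):
        rec, _ = make_plastome(PlastomeSpec(5000, 1500, 400, seed=1,
                                            gene_layout="custom"))
        part = partition_quadripartite(rec)
        anns = [GeneAnnotation("g1", "CDS", "+", [(4850, 4950)]),
                GeneAnnotation("g2", "CDS", "+", [(5050, 5150)])]
        report = junction_report(part, anns)
        e = report["JLB"]  # junction at 5000
        assert e.status == "intergenic"
        assert e.gene == "g1–g2"
        assert (e.left_bp, e.right_bp) == (50, 50)

    def test_empty_annotations(self):
        rec, _ = make_plastome(PlastomeSpec(5000, 1500, 400, seed=1,
                                            gene_layout="custom"))
        part = partition_quadripartite(rec)
        report = junction_report(part, [])
        for j in JUNCTIONS:
            assert report[j].status == "intergenic"
            assert report[j].gene is None
            assert report[j].left_bp is None

    def test_class_priority_cds_over_trna(self):
        rec, _ = make_plastome(PlastomeSpec(5000, 1500, 400, seed=1,
                                            gene_layout="custom"))
        part = partition_quadripartite(rec)
        anns = [GeneAnnotation("trnX", "tRNA", "+", [(4980, 5030)]),
                GeneAnnotation("geneY", "CDS", "+", [(4900, 5040)])]
        report = junction_report(part, anns)
        assert report["JLB"].gene == "geneY"

    def test_origin_spanning_gene_at_jla(self):
        rec, _ = make_plastome(PlastomeSpec(5000, 1500, 400, seed=1,
                                            gene_layout="custom"))
        part = partition_quadripartite(rec)
        L = part.total_len
        wrap = GeneAnnotation("trnH", "tRNA", "+", [(L - 30, L + 40)],
                              wraps_origin=True)
        report = junction_report(part, [wrap])
        assert report["JLA"].status == "gene_spans"
        assert report["JLA"].gene == "trnH"
        assert (report["JLA"].left_bp, report["JLA"].right_bp) == (30, 40)


class TestBoundaryShift:
    def test_jsb_shift_between_layouts(self):
        hoya, _ = make_plastome(hoya_like_spec(seed=0))
        outg, _ = make_plastome(outgroup_like_spec(seed=0))
        _, obs = _canonical_junction_genes(hoya)
        _, ref = _canonical_junction_genes(outg)
        shifts = {s.junction: s for s in classify_boundary_shift(obs, ref)}
        assert shifts["JSB"].shifted
        assert shifts["JSB"].reference_context == "ycf1"
        assert shifts["JSB"].observed_context == "ndhF"
        assert not shifts["JLB"].shifted  # rpl22 in both layouts

    def test_self_comparison_all_false(self):
        rec, _ = make_plastome(hoya_like_spec(seed=4))
        _, report = _canonical_junction_genes(rec)
        assert all(not s.shifted
                   for s in classify_boundary_shift(report, report))

    def test_single_junction_difference(self):
        # outgroup pair differing only at JLB: a gene there vs an
        # intergenic flanking pair
        rec, _ = make_plastome(outgroup_like_spec(seed=0))
        part, ref = _canonical_junction_genes(rec)
        anns = [remap_annotation(a, part.rotation_offset, len(rec.sequence))
                for a in rec.annotations]
        no_rpl22 = [a for a in anns if a.gene != "rpl22"]
        no_rpl22.append(GeneAnnotation("rps19", "CDS", "+",
                                       [(part.lsc[1] - 400, part.lsc[1] - 120)]))
        no_rpl22.append(GeneAnnotation("rpl2", "CDS", "+",
                                       [(part.lsc[1] + 80, part.lsc[1] + 380)]))
        obs = junction_report(part, no_rpl22)
        assert obs["JLB"].gene == "rps19–rpl2"
        shifts = {s.junction: s.shifted
                  for s in classify_boundary_shift(obs, ref)}
        assert shifts == {"JLB": True, "JSB": False, "JSA": False, "JLA": False}


class TestGeneInventory:
    def test_duplicate_symbols(self):
        anns = [GeneAnnotation("ndhB", "CDS", "+", [(0, 10)]),
                GeneAnnotation("ndhB", "CDS", "-", [(50, 60)])]
        inv = gene_inventory(anns)
        assert (inv.cds_total, inv.cds_unique) == (2, 1)

    def test_empty(self):
        inv = gene_inventory([])
        assert (inv.cds_total, inv.rrna_total, inv.trna_total) == (0, 0, 0)

    def test_ir_duplicated_genes_count_twice(self):
        rec, truth = make_plastome(hoya_like_spec(seed=0))
        inv = gene_inventory(rec.annotations)
        # rrn16/rrn23 planted once per IR copy; trnV likewise
        assert (inv.rrna_total, inv.rrna_unique) == (4, 2)
        assert (inv.trna_total, inv.trna_unique) == (2, 1)
        # single-copy CDS: rpl22, ndhF, psbA, rbcL
        assert (inv.cds_total, inv.cds_unique) == (4, 4)
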