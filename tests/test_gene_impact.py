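import numpy as np
import pytest

from ppsv.gene_impact import (
    DEFAULT_MAX_SPAN,
    RegulatoryElement,
    annotate_fusion,
    annotate_sv,
    candidate_genes,
    classify_impact,
    depth_ratio,
    read_enhancers,
    read_gene_models,
)
from ppsv.sv_io import make_record
from conftest import toy_gene


# ---------------------------------------------------------------------------
# per-base brute-force oracle


def _bases(iv):
    return set(range(iv[0], iv[1] + 1))


def oracle_category(sv, gene, enhancers=(), promoter_size=1000):
    gene_bases = _bases((gene.start, gene.end)) if True else set()
    cds = set().union(*[_bases(c) for c in gene.cds_segments]) if gene.cds_segments else set()
    utr = set().union(*[_bases(u) for u in gene.utr_segments]) if gene.utr_segments else set()
    exon = set().union(*[_bases(e) for e in gene.exons])

    def on_chrom(bp):
        return bp.chrom == gene.chrom

    bp1, bp2 = sv.bp1, sv.bp2
    if sv.svtype == "TRA":
        affected = set()
    elif sv.svtype == "INS":
        affected = {bp1.pos} if on_chrom(bp1) else set()
    else:
        affected = _bases((min(bp1.pos, bp2.pos) + 1, max(bp1.pos, bp2.pos))) if on_chrom(bp1) else set()
    b1_in = on_chrom(bp1) and bp1.pos in gene_bases
    b2_in = on_chrom(bp2) and bp2.pos in gene_bases

    if sv.svtype == "DEL":
        if affected & cds:
            return "pLoF"
        if affected & utr:
            return "UTR"
        for intron in gene.introns:
            if affected and affected <= _bases(intron):
                return "intronic"
    elif sv.svtype == "DUP":
        if not b1_in and not b2_in and gene_bases and gene_bases <= affected:
            return "CG"
        if b1_in and b2_in:
            if bp1.pos in exon and bp2.pos in exon:
                return "pLoF"
            if any(_bases(e) <= affected for e in gene.exons):
                return "IED"
            return "partial_exon_DUP"
        if b1_in != b2_in:
            return "partial_gene_DUP"
    elif sv.svtype == "INV":
        if gene_bases and gene_bases <= affected and not b1_in and not b2_in:
            return "whole_gene_INV"
        if b1_in or b2_in:
            return "pLoF"
    elif sv.svtype == "TRA":
        if b1_in or b2_in:
            return "pLoF"
    elif sv.svtype == "INS":
        if on_chrom(bp1) and bp1.pos in cds:
            return "pLoF"
        if on_chrom(bp1) and bp1.pos in utr:
            return "UTR"
        if on_chrom(bp1) and bp1.pos in (gene_bases - exon):
            return "intronic"

    promoter = _bases(gene.promoter_window(promoter_size))
    for bp in (bp1, bp2):
        if on_chrom(bp) and bp.pos in promoter:
            return "promoter"
    for e in enhancers:
        if e.target_gene != gene.gene_id:
            continue
        for bp in (bp1, bp2):
            if e.contains(bp.chrom, bp.pos):
                return "enhancer"
    return "intergenic"


# ---------------------------------------------------------------------------
# decision-table cases


class TestClassifyDel:
    def test_cds_removal_is_plof(self):
        g = toy_gene()
        # delete exon 2 entirely (intron 1 midpoint to intron 2 midpoint)
        sv = make_record("d", g.chrom, g.exons[0][1] + 500, g.chrom,
                         g.exons[1][1] + 500, "DEL")
        assert classify_impact(sv, g).category == "pLoF"

    def test_utr_only_removal(self):
        g = toy_gene(utr=80)
        s = g.exons[0][0]
        sv = make_record("d", g.chrom, s + 5, g.chrom, s + 60, "DEL")
        assert classify_impact(sv, g).category == "UTR"

    def test_fully_intronic(self):
        g = toy_gene()
        i0 = g.introns[1]
        sv = make_record("d", g.chrom, i0[0] + 10, g.chrom, i0[0] + 200, "DEL")
        assert classify_impact(sv, g).category == "intronic"


class TestClassifyDup:
    def test_whole_gene_is_cg(self):
        g = toy_gene()
        sv = make_record("d", g.chrom, g.start - 2000, g.chrom, g.end + 2000, "DUP")
        assert classify_impact(sv, g).category == "CG"

    def test_both_breakpoints_in_exons_is_plof(self):
        g = toy_gene()
        sv = make_record("d", g.chrom, g.exons[1][0] + 50, g.chrom,
                         g.exons[2][0] + 50, "DUP")
        assert classify_impact(sv, g).category == "pLoF"

    def test_intronic_breakpoints_flanking_exon_is_ied(self):
        # the duplicated-exon example: both breakpoints intronic, exon inside
        g = toy_gene()
        sv = make_record("d", g.chrom, g.exons[1][1] + 500, g.chrom,
                         g.exons[2][1] + 500, "DUP")
        assert classify_impact(sv, g).category == "IED"

    def test_partial_exon_dup(self):
        g = toy_gene()
        sv = make_record("d", g.chrom, g.exons[0][1] + 500, g.chrom,
                         g.exons[1][0] + 50, "DUP")
        assert classify_impact(sv, g).category == "partial_exon_DUP"

    def test_partial_gene_dup(self):
        g = toy_gene()
        sv = make_record("d", g.chrom, g.start - 2000, g.chrom,
                         g.exons[1][1] + 500, "DUP")
        assert classify_impact(sv, g).category == "partial_gene_DUP"


class TestClassifyInvTra:
    def test_whole_gene_inv(self):
        g = toy_gene()
        sv = make_record("d", g.chrom, g.start - 2000, g.chrom, g.end + 2000, "INV")
        assert classify_impact(sv, g).category == "whole_gene_INV"

    def test_inv_breakpoint_in_intron_is_plof(self):
        g = toy_gene()
        sv = make_record("d", g.chrom, g.exons[0][1] + 500, g.chrom,
                         g.end + 5000, "INV")
        assert classify_impact(sv, g).category == "pLoF"

    def test_tra_breakpoint_in_gene_is_plof(self):
        g = toy_gene()
        sv = make_record("d", g.chrom, g.exons[0][1] + 500, "chr9", 5000, "TRA")
        assert classify_impact(sv, g).category == "pLoF"


class TestRegulatoryFallback:
    def test_promoter_plus_strand(self):
        g = toy_gene(strand="+")
        sv = make_record("d", g.chrom, g.start - 900, g.chrom, g.start - 400, "DEL")
        assert classify_impact(sv, g).category == "promoter"

    def test_promoter_minus_strand_mirrors(self):
        g = toy_gene(strand="-")
        sv = make_record("d", g.chrom, g.end + 400, g.chrom, g.end + 900, "DEL")
        assert classify_impact(sv, g).category == "promoter"
        # and the plus-strand window does NOT fire for a minus-strand gene
        sv2 = make_record("d2", g.chrom, g.start - 900, g.chrom, g.start - 400, "DEL")
        assert classify_impact(sv2, g).category != "promoter"

    def test_enhancer(self):
        g = toy_gene()
        enh = RegulatoryElement(g.chrom, 50_000, 51_000, "enhancer", g.gene_id)
        sv = make_record("d", g.chrom, 50_100, g.chrom, 50_300, "DEL")
        assert classify_impact(sv, g, [enh]).category == "enhancer"

    def test_intergenic(self):
        g = toy_gene()
        sv = make_record("d", g.chrom, 10_000, g.chrom, 10_500, "DEL")
        assert classify_impact(sv, g).category == "intergenic"

    def test_promoter_never_overlaps_gene_body(self):
        for strand in "+-":
            g = toy_gene(strand=strand)
            w = g.promoter_window()
            assert w[1] < g.start or w[0] > g.end


class TestCandidateGenes:
    def test_small_sv_takes_overlapping_genes(self):
        genes = [toy_gene("A", start=100_000), toy_gene("B", start=200_000)]
        sv = make_record("d", "chr1", 100_500, "chr1", 101_000, "DEL")
        assert [g.gene_id for g in candidate_genes(sv, genes)] == ["A"]

    def test_large_span_restricted_to_breakpoint_genes(self):
        # genes fully inside a >1 Mbp inversion are NOT candidates
        bp_gene = toy_gene("A", start=100_000)
        inside1 = toy_gene("B", start=500_000)
        inside2 = toy_gene("C", start=900_000)
        genes = [bp_gene, inside1, inside2]
        sv = make_record("d", "chr1", 100_500, "chr1", 100_500 + 3_428_552, "INV")
        assert [g.gene_id for g in candidate_genes(sv, genes)] == ["A"]

    def test_boundary_at_max_span(self):
        inside = toy_gene("B", start=500_000)
        sv = make_record("d", "chr1", 100_000, "chr1", 100_000 + DEFAULT_MAX_SPAN, "DEL")
        assert [g.gene_id for g in candidate_genes(sv, [inside])] == ["B"]

    def test_gene_desert(self):
        genes = [toy_gene("A", start=100_000)]
        sv = make_record("d", "chr1", 900_000, "chr1", 900_400, "DEL")
        assert candidate_genes(sv, genes) == []


class TestFusion:
    def test_fusion_label_order(self):
        a = toy_gene("AK8", chrom="chr9", start=132_870_000)
        d = toy_gene("DST", chrom="chr6", start=56_890_000)
        # widen the toy genes so the breakpoints land inside them
        a.end = 132_880_000
        d.end = 56_900_000
        sv = make_record("t", "chr9", 132_876_361, "chr6", 56_896_165, "TRA")
        assert annotate_fusion(sv, [a, d]) == "AK8-DST"

    def test_intergenic_partner_no_fusion(self):
        a = toy_gene("A")
        sv = make_record("t", a.chrom, a.exons[0][1] + 500, "chr9", 5_000, "TRA")
        assert annotate_fusion(sv, [a]) is None
        anns = annotate_sv(sv, [a])
        assert [x.category for x in anns] == ["pLoF"]

    def test_non_tra_no_fusion(self):
        a = toy_gene("A")
        sv = make_record("d", a.chrom, a.start, a.chrom, a.end, "DEL")
        assert annotate_fusion(sv, [a]) is None


class TestOracleEquivalence:
    def test_randomized_instances(self):
        rng = np.random.default_rng(2024)
        genes = []
        for k in range(12):
            genes.append(
                toy_gene(
                    f"G{k}",
                    chrom=f"chr{k % 2 + 1}",
                    strand="+-"[k % 2],
                    start=100_000 + (k // 2) * 50_000,
                    n_exons=int(rng.integers(3, 7)),
                    exon_len=int(rng.integers(120, 300)),
                    intron_len=int(rng.integers(600, 2_000)),
                )
            )
        enhancers = [
            RegulatoryElement(g.chrom, g.start - 8_000, g.start - 7_000,
                              "enhancer", g.gene_id)
            for g in genes[::3]
        ]
        checked = 0
        for _ in range(300):
            svtype = rng.choice(["DEL", "DUP", "INV", "INS", "TRA"])
            if rng.random() < 0.7:  # bias towards gene neighbourhoods
                anchor = genes[int(rng.integers(0, len(genes)))]
                chrom = anchor.chrom
                p1 = max(1, anchor.start + int(rng.integers(-15_000, 15_000)))
            else:
                chrom = f"chr{int(rng.integers(1, 3))}"
                p1 = int(rng.integers(80_000, 420_000))
            if svtype == "TRA":
                other = "chr2" if chrom == "chr1" else "chr1"
                sv = make_record("s", chrom, p1, other,
                                 int(rng.integers(80_000, 420_000)), "TRA")
            elif svtype == "INS":
                sv = make_record("s", chrom, p1, chrom, p1, "INS",
                                 insertion_seq="A" * 60)
            else:
                sv = make_record("s", chrom, p1, chrom,
                                 p1 + int(rng.integers(60, 40_000)), svtype)
            for gene in candidate_genes(sv, genes):
                got = classify_impact(sv, gene, enhancers).category
                want = oracle_category(sv, gene, enhancers)
                assert got == want, (sv, gene.gene_id, got, want)
                checked += 1
        assert checked > 100


class TestReaders:
    def test_gtf_round_trip_through_generator(self, default_bundle):
        bundle, _ = default_bundle
        models = read_gene_models(bundle.gtf)
        assert len(models) == 45
        m = models[0]
        assert m.exons and m.cds_segments
        # cds + utr = exons, per gene
        for model in models[:10]:
            total_exon = sum(e - s + 1 for s, e in model.exons)
            total_cds = sum(e - s + 1 for s, e in model.cds_segments)
            total_utr = sum(e - s + 1 for s, e in model.utr_segments)
            assert total_cds + total_utr == total_exon

    def test_bed_coordinate_conversion(self, tmp_path):
        bed = tmp_path / "e.bed"
        bed.write_text("chr1\t999\t2000\tG001\n")
        (e,) = read_enhancers(bed)
        assert (e.start, e.end) == (1000, 2000)
        assert e.target_gene == "G001"


class TestDepthRatio:
    def _track(self, inside_depth, flank_depth, lo=20_000, hi=21_000, n=60_000):
        track = np.full(n, float(flank_depth))
        track[lo:hi] = inside_depth
        return {"chr1": track}

    def test_het_del(self):
        depth = self._track(15, 30)
        sv = make_record("d", "chr1", 20_000, "chr1", 21_000, "DEL")
        assert depth_ratio(sv, depth) == pytest.approx(0.5)

    def test_het_dup(self):
        depth = self._track(45, 30)
        sv = make_record("d", "chr1", 20_000, "chr1", 21_000, "DUP")
        assert depth_ratio(sv, depth) == pytest.approx(1.5)

    def test_noisy_planted_reduction(self):
        rng = np.random.default_rng(1)
        n = 80_000
        base = rng.poisson(30, n).astype(float)
        lo, hi = 30_000, 34_000
        reduction = rng.uniform(0.44, 0.51)
        track = base.copy()
        track[lo:hi] *= 1 - reduction
        sv = make_record("d", "chr1", lo, "chr1", hi, "DEL")
        assert 0.49 <= depth_ratio(sv, {"chr1": track}) <= 0.56

    def test_flank_truncated_with_warning(self):
        depth = {"chr1": np.full(15_000, 30.0)}
        sv = make_record("d", "chr1", 2_000, "chr1", 3_000, "DEL")
        with pytest.warns(UserWarning, match="truncated"):
            depth_ratio(sv, depth)

    def test_rejects_other_types(self):
        sv = make_record("d", "chr1", 100, "chr2", 300, "TRA")
        with pytest.raises(ValueError):
            depth_ratio(sv, {"chr1": np.ones(10)})
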