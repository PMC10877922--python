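"""Gene mapping, coding consequences, hot spots, hypergeometric enrichment."""

import numpy as np
import pandas as pd
import pytest

from mgwaskit import genemap as gm


def _ann(models) -> gm.GeneAnnotation:
    return gm.GeneAnnotation(genes={g.gene_id: g for g in models})


class TestRegionMapping:
    @pytest.fixture()
    def toy_ann(self):
        return _ann([
            gm.GeneModel("g1", "chr1", 1000, 2000, "+",
                         exons=[(1000, 1200), (1500, 2000)]),
            gm.GeneModel("g2", "chr1", 5000, 6000, "+", exons=[(5100, 5900)]),
            gm.GeneModel("g3", "chr2", 100, 900, "-", exons=[(100, 900)]),
        ])

    def test_exon_start_coordinate_is_exonic(self, toy_ann):
        snps = pd.DataFrame({"chrom": ["chr1"], "pos": [1000]}, index=["s"])
        out = gm.map_snps_to_genes(snps, toy_ann)
        assert out.regions["s"] == "exon"

    def test_between_genes_intergenic(self, toy_ann):
        snps = pd.DataFrame({"chrom": ["chr1"], "pos": [3000]}, index=["s"])
        out = gm.map_snps_to_genes(snps, toy_ann)
        assert out.regions["s"] == "intergenic"

    def test_inside_gene_outside_exon_intronic(self, toy_ann):
        snps = pd.DataFrame({"chrom": ["chr1"], "pos": [1300]}, index=["s"])
        out = gm.map_snps_to_genes(snps, toy_ann)
        assert out.regions["s"] == "intron"

    def test_region_labels_partition_snps(self, toy_ann):
        rng = np.random.default_rng(0)
        snps = pd.DataFrame({
            "chrom": rng.choice(["chr1", "chr2"], 50),
            "pos": rng.integers(1, 7000, 50),
        }, index=[f"s{i}" for i in range(50)])
        out = gm.map_snps_to_genes(snps, toy_ann)
        assert set(out.regions.index) == set(snps.index)
        assert set(out.regions.unique()) <= {"exon", "intron", "intergenic"}

    def test_assignments_match_exhaustive_interval_scan(self, toy_ann):
        """100 SNPs vs the toy annotation against a brute-force scan."""
        rng = np.random.default_rng(3)
        snps = pd.DataFrame({
            "chrom": rng.choice(["chr1", "chr2", "chr3"], 100),
            "pos": rng.integers(1, 8000, 100),
        }, index=[f"s{i}" for i in range(100)])
        out = gm.map_snps_to_genes(snps, toy_ann)
        for snp, row in snps.iterrows():
            region = "intergenic"
            for g in toy_ann.genes.values():
                if g.chrom != row["chrom"]:
                    continue
                if any(s <= row["pos"] <= e for s, e in g.exons):
                    region = "exon"
                    break
                if g.start <= row["pos"] <= g.end:
                    region = "intron"
            assert out.regions[snp] == region

    def test_gene_feature_links_via_sets(self, toy_ann):
        snps = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [1100, 5500]},
                            index=["m1", "m2"])
        reference_of = pd.Series({"m1": "ref1", "m2": "ref2"})
        assoc = pd.DataFrame({"feature": ["fA", "fB"],
                              "reference_snp": ["ref1", "ref1"]})
        out = gm.map_snps_to_genes(snps, toy_ann, reference_of=reference_of,
                                   associations=assoc)
        got = set(map(tuple, out.gene_features.to_numpy()))
        assert got == {("g1", "fA"), ("g1", "fB")}


class TestVariantEffect:
    @pytest.fixture()
    def coding_scene(self):
        # + strand gene, CDS = ATG GAT TAA  (Met Asp Stop)
        seq = "NNNN" + "ATGGATTAA" + "NNNN"
        genome = {"chr1": seq}
        ann = _ann([gm.GeneModel("g1", "chr1", 5, 13, "+",
                                 exons=[(5, 13)], cds=[(5, 13, 0)])])
        return ann, genome

    def test_missense_asp_to_glu(self, coding_scene):
        """GAT -> GAG at the codon-2 third position: Asp -> Glu, missense."""
        ann, genome = coding_scene
        eff = gm.classify_variant_effect("s", "chr1", 10, "T", "G", ann, genome)
        assert eff.consequence == "missense"
        assert (eff.ref_aa, eff.alt_aa) == ("D", "E")

    def test_synonymous_gat_to_gac(self, coding_scene):
        ann, genome = coding_scene
        eff = gm.classify_variant_effect("s", "chr1", 10, "T", "C", ann, genome)
        assert eff.consequence == "synonymous"
        assert eff.ref_aa == eff.alt_aa == "D"

    def test_stop_gain_classified_other(self, coding_scene):
        ann, genome = coding_scene
        # GAT -> TAT is missense; GAT->TAA needs two changes; use codon1:
        # ATG -> no stop in one change at pos 5..7? A->T at 7: ATG->ATT (Ile)
        eff = gm.classify_variant_effect("s", "chr1", 7, "G", "T", ann, genome)
        assert eff.consequence == "missense"
        # codon 3 TAA (stop) -> TAC (Tyr): stop-loss -> other
        eff2 = gm.classify_variant_effect("s", "chr1", 13, "A", "C", ann, genome)
        assert eff2.consequence == "other"

    def test_intronic_snp_consequence_na(self):
        genome = {"chr1": "A" * 100}
        ann = _ann([gm.GeneModel("g1", "chr1", 10, 60, "+",
                                 exons=[(10, 20), (50, 60)],
                                 cds=[(10, 20, 0)])])
        eff = gm.classify_variant_effect("s", "chr1", 30, "A", "T", ann, genome)
        assert eff.consequence == "na"
        assert eff.region == "intron"

    def test_allele_mismatch_raises_with_locus(self, coding_scene):
        ann, genome = coding_scene
        with pytest.raises(ValueError, match="chr1:10"):
            gm.classify_variant_effect("s", "chr1", 10, "A", "G", ann, genome)

    def test_minus_strand_codon(self):
        # - strand gene over revcomp(ATGGATTAA) = TTAATCCAT at 5..13
        genome = {"chr1": "NNNN" + "TTAATCCAT" + "NNNN"}
        ann = _ann([gm.GeneModel("g1", "chr1", 5, 13, "-",
                                 exons=[(5, 13)], cds=[(5, 13, 0)])])
        # genome + strand base at pos 8 is 'A'; on - strand this is codon-2
        # third base T of GAT; A->C on + strand is T->G on - strand: Asp->Glu
        eff = gm.classify_variant_effect("s", "chr1", 8, "A", "C", ann, genome)
        assert eff.consequence == "missense"
        assert (eff.ref_aa, eff.alt_aa) == ("D", "E")


class TestHotspots:
    def _uniform_ann(self, n_genes, length, chrom="chr1", seed=0):
        rng = np.random.default_rng(seed)
        genes = []
        for i in range(n_genes):
            s = int(rng.integers(1, length))
            genes.append(gm.GeneModel(f"g{i}", chrom, s, s + 999, "+",
                                      exons=[(s, s + 999)]))
        return _ann(genes)

    def test_qualifying_window_thresholds(self):
        """12 associated among 100 genes in one window qualifies
        (freq 0.12 > 0.075 and count 12 > 10); 11 among 200 fails."""
        ann = self._uniform_ann(100, 4_000_000)
        met = {f"g{i}" for i in range(12)}
        spots = gm.detect_hotspots(ann, met, window_bp=5_000_000,
                                   step_bp=5_000_000)
        assert len(spots) == 1
        ann2 = self._uniform_ann(200, 4_000_000)
        met2 = {f"g{i}" for i in range(11)}
        assert gm.detect_hotspots(ann2, met2, window_bp=5_000_000,
                                  step_bp=5_000_000) == []

    def test_strict_inequalities(self):
        # exactly 10 associated among 100 -> count not > 10 -> fails
        ann = self._uniform_ann(100, 4_000_000)
        met = {f"g{i}" for i in range(10)}
        assert gm.detect_hotspots(ann, met, window_bp=5_000_000,
                                  step_bp=5_000_000) == []

    def test_planted_cluster_merges_to_single_hotspot(self):
        """One 6-Mb cluster of associated genes -> exactly one merged hot
        spot covering it, cross-checked against a non-sliding evaluation."""
        rng = np.random.default_rng(5)
        genes = []
        # background: 300 genes over 60 Mb, none associated
        for i in range(300):
            s = int(rng.integers(1, 60_000_000))
            genes.append(gm.GeneModel(f"bg{i}", "chr1", s, s + 999, "+",
                                      exons=[(s, s + 999)]))
        # cluster: 40 genes in [20 Mb, 26 Mb], 30 associated
        met = set()
        for i in range(40):
            s = int(rng.integers(20_000_000, 26_000_000))
            gid = f"cl{i}"
            genes.append(gm.GeneModel(gid, "chr1", s, s + 999, "+",
                                      exons=[(s, s + 999)]))
            if i < 30:
                met.add(gid)
        ann = _ann(genes)
        spots = gm.detect_hotspots(ann, met)
        assert len(spots) == 1
        spot = spots[0]
        assert spot.start <= 20_000_000 and spot.end >= 26_000_000
        assert spot.frequency == spot.metabolite_gene_count / spot.gene_count

        # oracle: disjoint 5-Mb bins (step = window) must flag bins inside
        disjoint = gm.detect_hotspots(ann, met, window_bp=5_000_000,
                                      step_bp=5_000_000)
        for d in disjoint:
            assert d.start >= spot.start - 5_000_000 and d.end <= spot.end + 5_000_000

    def test_step_equals_window_is_disjoint_binning(self):
        """Independent binning code gives the same qualifying windows."""
        rng = np.random.default_rng(9)
        starts = rng.integers(1, 20_000_000, 400)
        genes = [gm.GeneModel(f"g{i}", "chr1", int(s), int(s) + 500, "+",
                              exons=[(int(s), int(s) + 500)])
                 for i, s in enumerate(starts)]
        met = {f"g{i}" for i in range(400) if i % 3 == 0}
        ann = _ann(genes)
        spots = gm.detect_hotspots(ann, met, window_bp=2_000_000,
                                   step_bp=2_000_000, freq_min=0.3,
                                   count_min=5)
        # oracle binning
        bins = {}
        for i, s in enumerate(starts):
            b = (int(s) - 1) // 2_000_000
            bins.setdefault(b, [0, 0])
            bins[b][0] += 1
            bins[b][1] += f"g{i}" in met
        qual = sorted(b for b, (tot, m) in bins.items()
                      if m / tot > 0.3 and m > 5)
        # merge adjacent oracle bins
        merged = []
        for b in qual:
            if merged and b == merged[-1][1] + 1:
                merged[-1][1] = b
            else:
                merged.append([b, b])
        got = [(s.start, s.end) for s in spots]
        want = [(lo * 2_000_000 + 1, (hi + 1) * 2_000_000) for lo, hi in merged]
        assert got == want

    def test_chromosome_order_invariance(self):
        g1 = [gm.GeneModel(f"a{i}", "chrA", 1000 * i + 1, 1000 * i + 500, "+",
                           exons=[(1000 * i + 1, 1000 * i + 500)]) for i in range(30)]
        g2 = [gm.GeneModel(f"b{i}", "chrB", 1000 * i + 1, 1000 * i + 500, "+",
                           exons=[(1000 * i + 1, 1000 * i + 500)]) for i in range(30)]
        met = {f"a{i}" for i in range(15)} | {f"b{i}" for i in range(15)}
        s1 = gm.detect_hotspots(_ann(g1 + g2), met, window_bp=50_000,
                                step_bp=10_000, freq_min=0.075, count_min=10)
        s2 = gm.detect_hotspots(_ann(g2 + g1), met, window_bp=50_000,
                                step_bp=10_000, freq_min=0.075, count_min=10)
        assert [(s.chrom, s.start, s.end) for s in s1] == \
            [(s.chrom, s.start, s.end) for s in s2]

    def test_empty_annotation_rejected(self):
        with pytest.raises(ValueError):
            gm.detect_hotspots(_ann([]), set())


class TestEnrichment:
    def test_term_equal_to_universe_p_one(self):
        universe = {f"g{i}" for i in range(50)}
        table = gm.enrich_hypergeometric({"g0", "g1"}, {"t": set(universe)},
                                         universe)
        assert table.loc[0, "pvalue"] == pytest.approx(1.0)

    def test_exact_tail_enumeration_oracle(self):
        """5-gene set fully inside a 5-gene term, universe 100: p equals the
        exact enumeration of the two-tailed hypergeometric."""
        universe = {f"g{i}" for i in range(100)}
        term = {f"g{i}" for i in range(5)}
        table = gm.enrich_hypergeometric(term, {"t": term}, universe)
        from math import comb

        N, K, n = 100, 5, 5
        pmf = {x: comb(K, x) * comb(N - K, n - x) / comb(N, n)
               for x in range(0, min(K, n) + 1)}
        p_obs = pmf[5]
        expected = sum(v for v in pmf.values() if v <= p_obs * (1 + 1e-9))
        assert table.loc[0, "pvalue"] == pytest.approx(expected, rel=1e-9)

    def test_bh_identical_pvalues_unchanged(self):
        universe = {f"g{i}" for i in range(40)}
        terms = {f"t{j}": {f"g{i}" for i in range(40)} for j in range(6)}
        table = gm.enrich_hypergeometric({"g0"}, terms, universe)
        np.testing.assert_allclose(table["p_adj"], table["pvalue"])

    def test_stray_genes_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            gm.enrich_hypergeometric({"x"}, {}, {"g1"})

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            gm.enrich_hypergeometric(set(), {}, set())


def test_variant_effect_from_indexed_fasta(tmp_path):
    """The classifier accepts a pyfaidx-indexed genome FASTA."""
    from mgwaskit import io as mio

    fa = tmp_path / "toy.fa"
    fa.write_text(">chr1\n" + "NNNN" + "ATGGATTAA" + "NNNN" + "\n")
    genome = mio.read_genome_fasta(fa)
    ann = _ann([gm.GeneModel("g1", "chr1", 5, 13, "+",
                             exons=[(5, 13)], cds=[(5, 13, 0)])])
    eff = gm.classify_variant_effect("s", "chr1", 10, "T", "G", ann, genome)
    assert eff.consequence == "missense"


class TestGff3:
    def test_roundtrip_via_gffutils(self, tmp_path):
        gff = tmp_path / "toy.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t100\t900\t.\t+\t.\tID=geneA\n"
            "chr1\tsrc\tmRNA\t100\t900\t.\t+\t.\tID=mrnaA;Parent=geneA\n"
            "chr1\tsrc\texon\t100\t400\t.\t+\t.\tID=exA1;Parent=mrnaA\n"
            "chr1\tsrc\texon\t500\t900\t.\t+\t.\tID=exA2;Parent=mrnaA\n"
            "chr1\tsrc\tCDS\t150\t400\t.\t+\t0\tID=cdsA1;Parent=mrnaA\n"
            "chr1\tsrc\tCDS\t500\t651\t.\t+\t1\tID=cdsA2;Parent=mrnaA\n")
        ann = gm.GeneAnnotation.from_gff3(gff)
        g = ann.genes["geneA"]
        assert (g.start, g.end, g.strand) == (100, 900, "+")
        assert g.exons == [(100, 400), (500, 900)]
        assert [c[:2] for c in g.cds] == [(150, 400), (500, 651)]
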