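"""Differential-analysis contracts: union merge, RPM counting, ranking,
gene assignment, classification, repeat filtering, footprints."""

import numpy as np
import pytest

from chromdiff.chromatin_diff import (
    DifferentialConfig,
    FootprintProfile,
    classify_regions,
    count_rpm,
    filter_simple_repeats,
    merge_peak_regions,
    nearest_tss,
    normalize_footprints,
    peak_gene_presence,
    rank_differential,
    repeat_coverage_fraction,
    tss_footprint,
    tss_peak_agreement,
)
from chromdiff.io_formats import AlignedRead, GeneModel, GenomicInterval
from chromdiff.peakcalling import Peak

CFG = DifferentialConfig(n_top=5)


def mk_peak(chrom, start, end, height=10, rpm=None):
    p = Peak(GenomicInterval(chrom, start, end), (start + end) // 2, height)
    p.height_rpm = rpm if rpm is not None else float(height)
    return p


class TestMerge:
    def test_single_sample_region_keeps_source(self):
        (reg,) = merge_peak_regions([mk_peak("chr1", 100, 200)], [])
        assert (reg.start, reg.end, reg.name) == (100, 200, "control")

    def test_overlap_across_samples_merges(self):
        (reg,) = merge_peak_regions(
            [mk_peak("chr1", 100, 200)], [mk_peak("chr1", 150, 250)]
        )
        assert (reg.start, reg.end, reg.name) == (100, 250, "both")

    def test_matches_sweep_line_union(self):
        rng = np.random.default_rng(30)

        def rand_peaks(n):
            out = []
            for _ in range(n):
                s = int(rng.integers(0, 5_000))
                out.append(mk_peak(f"chr{rng.integers(1, 3)}", s,
                                   s + int(rng.integers(50, 400))))
            return out

        a, b = rand_peaks(40), rand_peaks(40)
        merged = merge_peak_regions(a, b)
        # oracle: per-base paint then run-extract
        for chrom in ("chr1", "chr2"):
            paint = np.zeros(6_000, dtype=bool)
            for p in a + b:
                if p.chrom == chrom:
                    paint[p.interval.start : p.interval.end] = True
            got = [(r.start, r.end) for r in merged if r.chrom == chrom]
            padded = np.concatenate(([0], paint.view(np.int8), [0]))
            d = np.diff(padded)
            expect = list(zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)))
            assert got == [(int(s), int(e)) for s, e in expect]


class TestCountRpm:
    def test_definition(self):
        region = [GenomicInterval("chr1", 100, 200)]
        reads = [AlignedRead("chr1", 90 + 10 * i, 140 + 10 * i, "+") for i in range(5)]
        assert count_rpm(region, reads, 10**6)[0] == pytest.approx(5.0)
        assert count_rpm(region, [], 10**6)[0] == 0.0
        with pytest.raises(ValueError):
            count_rpm(region, reads, 0)

    def test_matches_brute_force_overlap(self):
        rng = np.random.default_rng(31)
        regions = [GenomicInterval("chr1", int(s), int(s) + int(w))
                   for s, w in zip(rng.integers(0, 9_000, 30),
                                   rng.integers(20, 500, 30))]
        reads = [AlignedRead("chr1", int(s), int(s) + 50, "+")
                 for s in rng.integers(0, 9_950, 400)]
        got = count_rpm(regions, reads, 400)
        for reg, val in zip(regions, got):
            brute = sum(1 for r in reads if r.start < reg.end and r.end > reg.start)
            assert val == pytest.approx(brute * 1e6 / 400)

    def test_rpm_invariant_under_depth_doubling(self):
        regions = [GenomicInterval("chr1", 0, 100)]
        reads = [AlignedRead("chr1", 10, 60, "+")] * 4
        once = count_rpm(regions, reads, 100)
        twice = count_rpm(regions, reads + reads, 200)
        assert twice[0] == pytest.approx(2 * once[0] / 2 * 2 / 2)  # = once
        assert twice[0] == pytest.approx(once[0] * 2 / 2)


class TestRankDifferential:
    def _regions(self, n, rng):
        return [GenomicInterval("chr1", 1000 * i, 1000 * i + 500) for i in range(n)]

    def test_ties_fill_by_genomic_order(self):
        rng = np.random.default_rng(32)
        regions = self._regions(8, rng)
        up, down = rank_differential(regions, [1.0] * 8, [1.0] * 8, CFG)
        assert [d.region.start for d in up] == [0, 1000, 2000, 3000, 4000]
        assert [d.region.start for d in up] == [d.region.start for d in down]

    def test_label_swap_swaps_lists(self):
        rng = np.random.default_rng(33)
        regions = self._regions(20, rng)
        a = rng.random(20) * 10
        b = rng.random(20) * 10
        up1, down1 = rank_differential(regions, a, b, CFG)
        up2, down2 = rank_differential(regions, b, a, CFG)
        assert [d.region.start for d in up1] == [d.region.start for d in down2]
        assert [d.region.start for d in down1] == [d.region.start for d in up2]

    def test_matches_brute_force_sort(self):
        rng = np.random.default_rng(34)
        regions = self._regions(50, rng)
        a = rng.random(50)
        b = rng.random(50)
        up, down = rank_differential(regions, a, b, CFG)
        delta = b - a
        expect_up = sorted(range(50), key=lambda i: (-delta[i], regions[i].start))[:5]
        assert [d.region.start for d in up] == [regions[i].start for i in expect_up]
        assert all(d.direction == "higher_in_patient" for d in up)
        assert [d.rank for d in up] == [1, 2, 3, 4, 5]

    def test_disjoint_when_deltas_nonzero(self):
        rng = np.random.default_rng(35)
        regions = self._regions(30, rng)
        a = np.arange(30, dtype=float)
        b = a + np.where(rng.random(30) < 0.5, 1.0, -1.0)
        up, down = rank_differential(regions, a, b, CFG)
        assert not ({d.region.start for d in up} & {d.region.start for d in down})


class TestNearestTss:
    GENES = [
        GeneModel("gB", "chr1", "+", 1_000, 2_000),
        GeneModel("gA", "chr1", "-", 5_000, 4_000),
        GeneModel("gC", "chr2", "+", 100, 500),
    ]

    def test_midpoint_at_tss_distance_zero(self):
        gene, dist = nearest_tss(GenomicInterval("chr1", 900, 1_100), self.GENES)
        assert gene == "gB" and dist == 0

    def test_equidistant_tie_smaller_gene_id(self):
        genes = [GeneModel("gB", "chr1", "+", 900, 1_500),
                 GeneModel("gA", "chr1", "+", 1_100, 1_500)]
        gene, _ = nearest_tss(GenomicInterval("chr1", 950, 1_050), genes)
        assert gene == "gA"

    def test_sign_negative_when_tss_upstream_of_midpoint(self):
        # + strand gene, region downstream of the TSS: TSS is upstream
        gene, dist = nearest_tss(GenomicInterval("chr1", 1_100, 1_300), self.GENES)
        assert gene == "gB" and dist == -200
        # - strand gene, region at lower coordinates is downstream of its TSS
        gene, dist = nearest_tss(GenomicInterval("chr1", 4_500, 4_900), self.GENES)
        assert gene == "gA" and dist == -300

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(36)
        genes = [
            GeneModel(f"g{i:03d}", "chr1", "+", int(t), int(t) + 100)
            for i, t in enumerate(rng.integers(0, 50_000, 40))
        ]
        for _ in range(50):
            s = int(rng.integers(0, 49_000))
            region = GenomicInterval("chr1", s, s + int(rng.integers(10, 900)))
            gene, dist = nearest_tss(region, genes)
            best = min(genes, key=lambda g: (abs(g.tss - region.midpoint), g.gene_id))
            assert gene == best.gene_id
            assert abs(dist) == abs(best.tss - region.midpoint)

    def test_empty_annotation_errors(self):
        with pytest.raises(ValueError):
            nearest_tss(GenomicInterval("chr3", 0, 10), self.GENES)


class TestClassify:
    GENES = [GeneModel("g1", "chr1", "+", 10_000, 14_000)]

    def test_region_at_tss_is_proximal_and_intragenic(self):
        (lab,) = classify_regions(
            [GenomicInterval("chr1", 9_900, 10_100)], self.GENES, CFG
        )
        assert lab == {"tss_class": "tss_proximal", "gene_class": "intragenic"}

    def test_gene_free_chromosome(self):
        (lab,) = classify_regions([GenomicInterval("chrY", 0, 100)], self.GENES, CFG)
        assert lab == {"tss_class": "non_tss", "gene_class": "intergenic"}

    def test_matches_brute_window_tests(self):
        rng = np.random.default_rng(37)
        genes = []
        for i, a in enumerate(rng.integers(3_000, 80_000, 15)):
            lo, hi = int(a), int(a) + int(rng.integers(500, 5_000))
            if rng.random() < 0.5:
                genes.append(GeneModel(f"g{i}", "chr1", "+", lo, hi))
            else:
                genes.append(GeneModel(f"g{i}", "chr1", "-", hi, lo))
        regions = [GenomicInterval("chr1", int(s), int(s) + int(w))
                   for s, w in zip(rng.integers(0, 90_000, 60),
                                   rng.integers(50, 3_000, 60))]
        labels = classify_regions(regions, genes, CFG)
        for reg, lab in zip(regions, labels):
            tss_hit = any(
                reg.start < g.tss + 2_000 and g.tss - 2_000 < reg.end for g in genes
            )
            body_hit = any(
                reg.start < max(g.tss, g.tes) + 1 and min(g.tss, g.tes) < reg.end
                for g in genes
            )
            assert (lab["tss_class"] == "tss_proximal") == tss_hit
            assert (lab["gene_class"] == "intragenic") == body_hit

    def test_labels_partition_each_axis(self):
        rng = np.random.default_rng(38)
        regions = [GenomicInterval("chr1", int(s), int(s) + 100)
                   for s in rng.integers(0, 50_000, 40)]
        for lab in classify_regions(regions, self.GENES, CFG):
            assert lab["tss_class"] in ("tss_proximal", "non_tss")
            assert lab["gene_class"] in ("intragenic", "intergenic")


class TestRepeatFilter:
    def test_strict_boundary(self):
        region = GenomicInterval("chr1", 0, 100)
        exactly_80 = [GenomicInterval("chr1", 0, 80)]
        over_80 = [GenomicInterval("chr1", 0, 85)]
        kept, n = filter_simple_repeats([region], exactly_80, CFG)
        assert kept == [region] and n == 0
        kept, n = filter_simple_repeats([region], over_80, CFG)
        assert kept == [] and n == 1

    def test_union_coverage_not_double_counted(self):
        region = GenomicInterval("chr1", 0, 100)
        repeats = [GenomicInterval("chr1", 0, 50), GenomicInterval("chr1", 30, 70)]
        assert repeat_coverage_fraction(region, repeats) == pytest.approx(0.7)

    def test_matches_base_coverage_oracle(self):
        rng = np.random.default_rng(39)
        repeats = [GenomicInterval("chr1", int(s), int(s) + int(w))
                   for s, w in zip(rng.integers(0, 9_500, 40),
                                   rng.integers(10, 400, 40))]
        regions = [GenomicInterval("chr1", int(s), int(s) + int(w))
                   for s, w in zip(rng.integers(0, 9_000, 50),
                                   rng.integers(50, 800, 50))]
        kept, _ = filter_simple_repeats(regions, repeats, CFG)
        paint = np.zeros(10_000, dtype=bool)
        for r in repeats:
            paint[r.start : r.end] = True
        expect = [r for r in regions
                  if paint[r.start : r.end].mean() <= 0.8]
        assert kept == expect


class TestFootprint:
    CFG = DifferentialConfig(footprint_halfwidth=1000)

    def test_zero_reads_zero_vector(self):
        genes = [GeneModel("g1", "chr1", "+", 5_000, 9_000)]
        prof = tss_footprint([], genes, self.CFG, chrom_sizes={"chr1": 20_000})
        assert prof.values.shape == (2001,) and prof.values.sum() == 0

    def test_single_read_single_gene_identity(self):
        genes = [GeneModel("g1", "chr1", "+", 5_000, 9_000)]
        reads = [AlignedRead("chr1", 5_000, 5_050, "+")]
        prof = tss_footprint(reads, genes, self.CFG, chrom_sizes={"chr1": 20_000})
        np.testing.assert_array_equal(prof.values[1000:1050], np.ones(50))
        assert prof.values.sum() == 50

    def test_minus_strand_gene_flipped(self):
        genes = [GeneModel("g1", "chr1", "-", 9_000, 5_000)]
        reads = [AlignedRead("chr1", 9_001, 9_051, "+")]  # downstream in genome
        prof = tss_footprint(reads, genes, self.CFG, chrom_sizes={"chr1": 20_000})
        # read sits at genomic offsets +1..+50; flipped to -50..-1
        assert prof.values[950:1000].sum() == 50
        assert prof.values[1001:].sum() == 0
        unflipped = tss_footprint(reads, genes, self.CFG, flip_minus_strand=False,
                                  chrom_sizes={"chr1": 20_000})
        assert unflipped.values[1001:1051].sum() == 50

    def test_matches_window_extraction_oracle(self):
        rng = np.random.default_rng(40)
        genes = [
            GeneModel(f"g{i}", "chr1", "+" if rng.random() < 0.5 else "-",
                      int(t) if rng.random() < 2 else int(t), int(t))
            for i, t in enumerate(rng.integers(2_000, 18_000, 20))
        ]
        genes = [GeneModel(g.gene_id, "chr1", g.strand,
                           g.tss, g.tss + 500 if g.strand == "+" else g.tss - 500)
                 for g in genes]
        reads = [AlignedRead("chr1", int(s), int(s) + 50, "+")
                 for s in rng.integers(0, 19_950, 500)]
        prof = tss_footprint(reads, genes, self.CFG, chrom_sizes={"chr1": 20_000})
        cov = np.zeros(20_000)
        for r in reads:
            cov[r.start : r.end] += 1
        acc = np.zeros(2001)
        for g in genes:
            win = np.zeros(2001)
            lo, hi = g.tss - 1000, g.tss + 1001
            win[max(0, lo) - lo : min(20_000, hi) - lo] = cov[max(0, lo):min(20_000, hi)]
            acc += win[::-1] if g.strand == "-" else win
        np.testing.assert_allclose(prof.values, acc / len(genes))

    def test_no_protein_coding_genes_errors(self):
        genes = [GeneModel("g1", "chr1", "+", 100, 500, "lincRNA")]
        with pytest.raises(ValueError):
            tss_footprint([], genes, self.CFG)


class TestNormalizeFootprints:
    def test_uniform_profile_becomes_all_ones(self):
        p = FootprintProfile("m", np.full(2001, 7.0), 10)
        (out,) = normalize_footprints([p])
        np.testing.assert_allclose(out.values, 1.0)

    def test_sum_and_global_max_identities(self):
        rng = np.random.default_rng(41)
        profiles = [FootprintProfile(m, rng.random(2001) + 0.1, 5)
                    for m in ("a", "b", "c")]
        out = normalize_footprints(profiles)
        gmax = max(float(o.values.max()) for o in out)
        assert gmax == pytest.approx(1.0, abs=1e-12)
        sums = [o.values.sum() for o in out]
        # all step-1 sums were equal, so post-scaling sums stay equal
        assert max(sums) - min(sums) < 1e-9 * 2001
        assert any(float(o.values.max()) == pytest.approx(1.0) for o in out)

    def test_idempotent_on_normalized_input(self):
        rng = np.random.default_rng(42)
        profiles = [FootprintProfile(m, rng.random(2001) + 0.1, 5)
                    for m in ("a", "b")]
        once = normalize_footprints(profiles)
        twice = normalize_footprints(once)
        for a, b in zip(once, twice):
            np.testing.assert_allclose(a.values, b.values, rtol=1e-12)

    def test_mark_ratios_preserved_from_step1(self):
        rng = np.random.default_rng(43)
        profiles = [FootprintProfile(m, rng.random(101) + 0.5, 5)
                    for m in ("a", "b")]
        out = normalize_footprints(profiles)
        s1 = [p.values * (101 / p.values.sum()) for p in profiles]
        expect_ratio = s1[0] / s1[1]
        np.testing.assert_allclose(out[0].values / out[1].values, expect_ratio)

    def test_all_zero_profile_errors(self):
        with pytest.raises(ValueError, match="zero"):
            normalize_footprints([FootprintProfile("m", np.zeros(101), 3)])


class TestPresenceAndAgreement:
    GENES = [GeneModel("g1", "chr1", "+", 10_000, 15_000),
             GeneModel("g2", "chr1", "+", 40_000, 45_000)]

    def test_presence_categories(self):
        pc = [mk_peak("chr1", 9_500, 10_500)]
        pp = [mk_peak("chr1", 9_000, 9_800), mk_peak("chr1", 39_000, 39_500)]
        counts = peak_gene_presence(pc, pp, self.GENES, CFG)
        assert counts == {"both": 1, "control_only": 0, "patient_only": 1}
        assert peak_gene_presence([], [], self.GENES, CFG) == {
            "both": 0, "control_only": 0, "patient_only": 0}

    def test_identical_peak_sets_perfect_agreement(self):
        rng = np.random.default_rng(44)
        peaks = []
        for t in (10_000, 40_000):
            for off in (-100, 40, 900):
                p = mk_peak("chr1", t + off - 50, t + off + 50,
                            rpm=float(rng.random() * 9 + 1))
                peaks.append(p)
        out = tss_peak_agreement(peaks, peaks, self.GENES, CFG)
        assert out["r"] == pytest.approx(1.0)
        assert out["fraction_matched"] == 1.0

    def test_disjoint_chromosomes(self):
        a = [mk_peak("chr1", 9_900, 10_100)]
        b = [mk_peak("chr9", 9_900, 10_100)]
        out = tss_peak_agreement(a, b, self.GENES, CFG)
        assert out["fraction_matched"] == 0.0 and out["r"] is None

    def test_correlated_heights_recovered(self):
        rng = np.random.default_rng(45)
        genes = [GeneModel(f"g{i}", "chr1", "+", 20_000 * (i + 1),
                           20_000 * (i + 1) + 1_000) for i in range(30)]
        shared = rng.random(30) * 10 + 5
        a, b = [], []
        for i, g in enumerate(genes):
            a.append(mk_peak("chr1", g.tss - 60, g.tss + 60,
                             rpm=float(shared[i] + rng.normal(0, 0.5))))
            b.append(mk_peak("chr1", g.tss - 55, g.tss + 65,
                             rpm=float(shared[i] + rng.normal(0, 0.5))))
        out = tss_peak_agreement(a, b, genes, CFG)
        assert out["n_pairs"] == 30 and out["r"] > 0.9
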