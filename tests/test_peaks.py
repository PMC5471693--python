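"""Feature maps, peak densities, sex overlap sets and ploidy coverage ratios."""
import numpy as np
import pytest

from aphidx.io_formats import Peak, SignalTrack
from aphidx.peaks import (FEATURES, build_feature_map, chrom_coverage_ratio,
                          intergenic_peaks, merge_intervals, overlap_sets,
                          peak_density)
from conftest import make_annotation, simple_gene


def _plus_gene_with_utr():
    # + strand gene [5000, 8000): 5'UTR [5000,5200), CDS [5200,7000) & [7400,7800),
    # intron [7000,7400), 3'UTR [7800,8000)
    from aphidx.io_formats import GeneModel
    return GeneModel("g1", "s", "+", 5000, 8000,
                     exons=[(5000, 7000), (7400, 8000)],
                     cds=[(5200, 7000), (7400, 7800)],
                     utr5=[(5000, 5200)], utr3=[(7800, 8000)])


class TestFeatureMap:
    def test_plus_strand_upstream_windows(self):
        ann = make_annotation({"s": 20000}, {"s": "A"}, [_plus_gene_with_utr()])
        fm = build_feature_map(ann)
        assert fm.intervals["tss"]["s"].tolist() == [[4800, 5000]]
        assert fm.intervals["promoter"]["s"].tolist() == [[3700, 4800]]
        assert fm.intervals["intron"]["s"].tolist() == [[7000, 7400]]

    def test_untrimmed_promoter_includes_tss_window(self):
        ann = make_annotation({"s": 20000}, {"s": "A"}, [_plus_gene_with_utr()])
        fm = build_feature_map(ann, trim_promoter=False)
        assert fm.intervals["promoter"]["s"].tolist() == [[3700, 5000]]

    def test_minus_strand_windows_mirrored(self):
        from aphidx.io_formats import GeneModel
        g = GeneModel("g2", "s", "-", 5000, 8000,
                      exons=[(5000, 8000)], cds=[(5200, 7800)],
                      utr5=[(7800, 8000)], utr3=[(5000, 5200)])
        ann = make_annotation({"s": 20000}, {"s": "A"}, [g])
        fm = build_feature_map(ann)
        # first 5'UTR base (transcript orientation) is 7999; upstream is rightward
        assert fm.intervals["tss"]["s"].tolist() == [[8000, 8200]]
        assert fm.intervals["promoter"]["s"].tolist() == [[8200, 9300]]

    def test_promoter_clipped_at_scaffold_start(self):
        g = simple_gene("g", "s", "+", 100, 600, utr5=[(100, 150)])
        ann = make_annotation({"s": 20000}, {"s": "A"}, [g])
        # untrimmed promoter [-1200, 100) clips to [0, 100)
        fm = build_feature_map(ann, trim_promoter=False)
        assert fm.intervals["promoter"]["s"].tolist() == [[0, 100]]
        # with trimming the whole [TSS-1300, TSS-200) window is off-scaffold
        fm2 = build_feature_map(ann)
        assert fm2.intervals["promoter"]["s"].size == 0
        assert fm2.intervals["tss"]["s"].tolist() == [[0, 100]]

    def test_utrless_gene_flagged_and_anchored_at_gene_start(self):
        g = simple_gene("g", "s", "+", 5000, 6000)
        ann = make_annotation({"s": 20000}, {"s": "A"}, [g])
        fm = build_feature_map(ann)
        assert fm.flagged_genes == ["g"]
        assert fm.intervals["tss"]["s"].tolist() == [[4800, 5000]]
        assert not build_feature_map(ann, skip_utrless=True).intervals["tss"]["s"].size

    def test_intergenic_is_exact_complement(self):
        ann = make_annotation({"s": 20000}, {"s": "A"}, [_plus_gene_with_utr()])
        fm = build_feature_map(ann)
        covered = sum(fm.lengths_bp[f] for f in FEATURES)
        assert covered == 20000  # disjoint trimmed features + complement tile exactly


class TestPeakDensity:
    def test_single_peak_in_megabase_feature(self):
        g = simple_gene("g", "s", "+", 0, 1_000_000, utr5=[(0, 10)],
                        cds=[(10, 1_000_000)])
        ann = make_annotation({"s": 2_000_000}, {"s": "A"}, [g])
        fm = build_feature_map(ann)
        peaks = [Peak("s", 500_000, 500_400, 500_200, "male")]
        dens = peak_density(peaks, fm).set_index(["feature", "sex"])
        assert np.isclose(dens.loc[("cds", "male"), "density_per_mb"], 1.0, rtol=1e-4)

    def test_boundary_spanning_peak_counts_in_both(self):
        ann = make_annotation({"s": 20000}, {"s": "A"}, [_plus_gene_with_utr()])
        fm = build_feature_map(ann)
        peaks = [Peak("s", 6950, 7050, 7000, "male")]  # spans CDS/intron boundary
        dens = peak_density(peaks, fm).set_index(["feature", "sex"])
        assert dens.loc[("cds", "male"), "peak_count"] == 1
        assert dens.loc[("intron", "male"), "peak_count"] == 1

    def test_counts_match_per_base_oracle(self):
        rng = np.random.default_rng(6)
        ann = make_annotation({"s": 1000}, {"s": "A"},
                              [simple_gene("g", "s", "+", 400, 700, utr5=[(400, 450)],
                                           utr3=[(650, 700)], cds=[(450, 650)])])
        fm = build_feature_map(ann)
        label = {f: np.zeros(1000, dtype=bool) for f in FEATURES}
        for f in FEATURES:
            for s, e in fm.intervals[f]["s"]:
                label[f][s:e] = True
        peaks = []
        for k in range(10):
            s = int(rng.integers(0, 960))
            peaks.append(Peak("s", s, s + int(rng.integers(5, 40)), s, "male"))
        dens = peak_density(peaks, fm).set_index(["feature", "sex"])
        for f in FEATURES:
            expected = sum(label[f][p.start:p.end].any() for p in peaks)
            assert dens.loc[(f, "male"), "peak_count"] == expected


class TestOverlapSets:
    def test_disjoint_sets(self):
        m = [Peak("s", 0, 10, 5, "male")]
        f = [Peak("s", 100, 110, 105, "female")]
        out = overlap_sets(m, f)
        assert out["shared_regions"] == 0
        assert out["male_specific"] == 1 and out["female_specific"] == 1
        assert out["n_union_regions"] == 2

    def test_identical_sets_fully_shared(self):
        m = [Peak("s", 0, 10, 5, "male"), Peak("s", 50, 60, 55, "male")]
        f = [Peak("s", 0, 10, 5, "female"), Peak("s", 50, 60, 55, "female")]
        out = overlap_sets(m, f)
        assert out["male_shared"] == 2 and out["female_shared"] == 2
        assert out["shared_regions"] == 2 and out["n_union_regions"] == 2

    def test_chained_overlaps_merge(self):
        m = [Peak("s", 0, 20, 10, "male"), Peak("s", 30, 50, 40, "male")]
        f = [Peak("s", 15, 35, 25, "female")]
        out = overlap_sets(m, f)
        assert out["n_union_regions"] == 1
        assert out["male_shared"] == 2 and out["female_shared"] == 1
        assert out["shared_regions"] == 1

    def test_shared_region_count_is_symmetric(self):
        rng = np.random.default_rng(8)
        def rand_peaks(sex, n):
            out = []
            for _ in range(n):
                s = int(rng.integers(0, 5000))
                out.append(Peak("s", s, s + int(rng.integers(10, 120)), s, sex))
            return sorted(out, key=lambda p: p.start)
        m, f = rand_peaks("male", 40), rand_peaks("female", 30)
        assert overlap_sets(m, f)["shared_regions"] == \
               overlap_sets(f, m)["shared_regions"]


class TestCoverageRatio:
    def test_equal_coverage_ratio_one(self):
        t = SignalTrack(10, {"a": np.full(100, 3.0), "x": np.full(100, 3.0)})
        assert chrom_coverage_ratio(t, {"a": "A", "x": "X"}) == 1.0

    def test_twofold_coverage(self):
        t = SignalTrack(10, {"a": np.full(100, 4.0), "x": np.full(100, 2.0)})
        assert chrom_coverage_ratio(t, {"a": "A", "x": "X"}) == 2.0

    def test_missing_class_errors(self):
        t = SignalTrack(10, {"a": np.full(100, 4.0)})
        with pytest.raises(ValueError):
            chrom_coverage_ratio(t, {"a": "A"})


def test_intergenic_peaks_filter(small_faire, small_sim):
    ann, _, _ = small_sim
    fm = build_feature_map(ann)
    inter = intergenic_peaks(small_faire.peaks, fm)
    assert inter  # the generator plants intergenic enrichment sites
    site_positions = set(zip(small_faire.sites["scaffold"], small_faire.sites["position"]))
    assert all((p.scaffold, p.summit) in site_positions for p in inter)
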