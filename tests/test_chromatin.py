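"""Signal normalization, metagene/summit profiles, bootstrap CIs, correlations."""
import numpy as np
import pandas as pd
import pytest

from aphidx.chromatin import (depth_normalize, expression_rank_order,
                              library_correlation, metagene, profile_ci,
                              signal_ratio, summit_matrix)
from aphidx.io_formats import Peak, SignalTrack
from conftest import make_annotation, simple_gene


def _track(arrays, bin_size=10, lengths=None):
    vals = {s: np.asarray(v, dtype=float) for s, v in arrays.items()}
    return SignalTrack(bin_size=bin_size, values=vals, lengths=lengths)


class TestDepthNormalize:
    def test_uniform_track_becomes_ones(self):
        t = depth_normalize(_track({"s": [4, 4, 4]}))
        assert np.allclose(t.values["s"], 1.0)

    def test_scale_invariance(self):
        a = _track({"s": [1, 2, 3, 4.0]})
        b = _track({"s": [2, 4, 6, 8.0]})
        assert np.allclose(depth_normalize(a).values["s"],
                           depth_normalize(b).values["s"])

    def test_genome_wide_not_per_scaffold_mean(self):
        t = depth_normalize(_track({"a": [3, 1], "b": [2, 2.0]}))  # mean 2
        assert np.allclose(t.values["a"], [1.5, 0.5])
        assert np.allclose(t.values["b"], [1.0, 1.0])

    def test_autosome_anchor_uses_only_autosomal_bins(self):
        t = _track({"a": [2, 2.0], "x": [1, 1.0]})
        out = depth_normalize(t, anchor="autosomes", chrom_class={"a": "A", "x": "X"})
        assert np.allclose(out.values["a"], 1.0)
        assert np.allclose(out.values["x"], 0.5)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            depth_normalize(_track({"s": [0, 0.0]}))


class TestSignalRatio:
    def test_equal_tracks_ratio_one(self):
        f = _track({"s": [1, 2, 5.0]})
        assert np.allclose(signal_ratio(f, f).values["s"], 1.0)

    def test_zero_over_zero_is_one(self):
        f = _track({"s": [0.0]})
        c = _track({"s": [0.0]})
        assert np.allclose(signal_ratio(f, c).values["s"], 1.0)

    def test_pseudocount_arithmetic(self):
        f = _track({"s": [2.0, 0.0]})
        c = _track({"s": [1.0, 4.0]})
        out = signal_ratio(f, c, pseudocount=0.5)
        assert np.allclose(out.values["s"], [2.5 / 1.5, 0.5 / 4.5])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            signal_ratio(_track({"s": [1.0]}), _track({"s": [1.0, 2.0]}))


def _ramp_track(n_bins=400):
    return _track({"s": np.arange(n_bins, dtype=float)})


class TestMetagene:
    def test_constant_signal_gives_constant_row_any_length(self):
        t = _track({"s": np.full(600, 3.7)})
        for strand, length in (("+", 1507), ("-", 733), ("+", 4210)):
            g = simple_gene("g", "s", strand, 1000, 1000 + length)
            row = metagene(t, [g]).values[0]
            assert np.allclose(row, 3.7)

    def test_strand_reversal_reverses_row(self):
        t = _ramp_track()
        gp = simple_gene("g", "s", "+", 1000, 2500)
        gm = simple_gene("g", "s", "-", 1000, 2500)
        rp = metagene(t, [gp]).values[0]
        rm = metagene(t, [gm]).values[0]
        assert np.allclose(rp, rm[::-1])

    def test_native_length_body_passes_through(self):
        t = _ramp_track()
        g = simple_gene("g", "s", "+", 1000, 2500)  # 1500 bp = 150 bins exactly
        mat = metagene(t, [g])
        assert np.allclose(mat.values[0][50:200], t.values["s"][100:250])
        assert np.allclose(mat.values[0][:50], t.values["s"][50:100])

    def test_resampling_conserves_body_mean(self):
        rng = np.random.default_rng(0)
        t = _track({"s": rng.uniform(0, 10, 500)})
        g = simple_gene("g", "s", "+", 730, 2980)
        mat = metagene(t, [g])
        body = mat.values[0][50:200]
        covering = t.values["s"][73:298]
        assert np.isclose(body.mean(), covering.mean())

    def test_scaffold_edge_clipping_yields_nan(self):
        t = _track({"s": np.ones(50)})
        g = simple_gene("g", "s", "+", 100, 400)  # upstream flank exceeds scaffold start
        row = metagene(t, [g]).values[0]
        assert np.isnan(row[:40]).all() and np.isfinite(row[40:50]).all()

    def test_sub_bin_gene_flagged(self):
        t = _track({"s": np.ones(100)})
        g = simple_gene("g", "s", "+", 505, 509)
        mat = metagene(t, [g])
        assert mat.meta.loc[0, "short"]
        assert np.isnan(mat.values[0]).all()


class TestSummitMatrix:
    def test_matches_direct_slicing(self):
        t = _ramp_track()
        p = Peak("s", 1900, 2100, 2005, "male")
        row = summit_matrix(t, [p]).values[0]
        assert np.allclose(row, t.values["s"][100:300])

    def test_symmetric_peak_symmetric_row(self):
        x = np.arange(400.0)
        # window [100, 300) of bins is symmetric about 199.5
        sym = np.exp(-0.5 * ((x - 199.5) / 8) ** 2)
        t = _track({"s": sym})
        row = summit_matrix(t, [Peak("s", 1950, 2050, 2004)]).values[0]
        assert np.allclose(row, row[::-1], atol=1e-12)

    def test_summit_position_quantized_to_bin(self):
        t = _ramp_track()
        r1 = summit_matrix(t, [Peak("s", 1900, 2100, 2000)]).values[0]
        r2 = summit_matrix(t, [Peak("s", 1900, 2100, 2009)]).values[0]
        assert np.allclose(r1, r2)

    def test_edge_clipping(self):
        t = _track({"s": np.ones(100)})
        row = summit_matrix(t, [Peak("s", 0, 200, 100)]).values[0]
        assert np.isnan(row[:90]).all() and np.isfinite(row[90:110]).all()


class TestProfileCI:
    def test_identical_rows_zero_width(self):
        m = np.tile(np.array([1.0, 5.0, 2.0]), (20, 1))
        ci = profile_ci(m, n_boot=200, seed=0)
        assert np.allclose(ci["lower"], ci["upper"])
        assert np.allclose(ci["mean"], [1, 5, 2])

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        m = rng.normal(5, 1, (100, 4))
        a = profile_ci(m, n_boot=300, seed=42)
        b = profile_ci(m, n_boot=300, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_mean_is_plain_column_mean_with_nans(self):
        m = np.array([[1.0, np.nan], [3.0, 4.0], [5.0, 8.0]])
        ci = profile_ci(m, n_boot=50, seed=0)
        assert np.allclose(ci["mean"], [3.0, 6.0])
        assert list(ci["n"]) == [3, 2]

    def test_too_few_rows_or_boots_rejected(self):
        with pytest.raises(ValueError):
            profile_ci(np.ones((1, 3)), n_boot=100, seed=0)
        with pytest.raises(ValueError):
            profile_ci(np.ones((5, 3)), n_boot=1, seed=0)

    def test_bounds_bracket_mean(self):
        rng = np.random.default_rng(2)
        m = rng.normal(0, 1, (200, 6))
        ci = profile_ci(m, n_boot=400, seed=3)
        assert ((ci["lower"] <= ci["mean"]) & (ci["mean"] <= ci["upper"])).all()


class TestRankOrdering:
    def _matrix(self, ids, chrom="A"):
        meta = pd.DataFrame({"id": ids, "scaffold": "s", "strand": "+",
                             "chrom_class": chrom, "short": False})
        from aphidx.chromatin import MetageneMatrix
        return MetageneMatrix(np.zeros((len(ids), 3)), meta, 1, 1, 1)

    def test_decreasing_expression_is_identity(self):
        mat = self._matrix(["a", "b", "c"])
        expr = pd.Series({"a": 30.0, "b": 20.0, "c": 10.0})
        assert list(expression_rank_order(mat, expr)) == [0, 1, 2]

    def test_permutation_invariant_result(self):
        mat = self._matrix(["a", "b", "c", "d"])
        expr = pd.Series({"a": 5.0, "b": 50.0, "c": 1.0, "d": 20.0})
        order = expression_rank_order(mat, expr)
        assert [mat.meta.loc[i, "id"] for i in order] == ["b", "d", "a", "c"]

    def test_ties_broken_by_id(self):
        mat = self._matrix(["z", "y", "x"])
        expr = pd.Series({"z": 1.0, "y": 1.0, "x": 1.0})
        order = expression_rank_order(mat, expr)
        assert [mat.meta.loc[i, "id"] for i in order] == ["x", "y", "z"]


class TestLibraryCorrelation:
    def _cov(self, seed, n=6000):
        rng = np.random.default_rng(seed)
        return _track({"s": rng.uniform(0, 10, n)})

    def test_duplicate_library_perfectly_correlated_and_first_merged(self):
        a = self._cov(0)
        tracks = {"lib1": a, "lib1_dup": a, "lib2": self._cov(1)}
        r, link = library_correlation(tracks, [("s", 0, 60000)])
        assert np.isclose(r.loc["lib1", "lib1_dup"], 1.0)
        assert set(link[0][:2].astype(int)) == {0, 1}  # the duplicates merge first

    def test_scaled_library_still_r_one(self):
        a = self._cov(2)
        b = _track({"s": a.values["s"] * 3})
        r, _ = library_correlation({"a": a, "b": b, "c": self._cov(3)},
                                   [("s", 0, 60000)])
        assert np.isclose(r.loc["a", "b"], 1.0)

    def test_independent_libraries_near_zero(self):
        tracks = {f"l{i}": self._cov(10 + i) for i in range(3)}
        r, _ = library_correlation(tracks, [("s", 0, 50000)])
        off = r.to_numpy()[~np.eye(3, dtype=bool)]
        assert (np.abs(off) < 0.2).all()

    def test_zero_variance_names_library(self):
        tracks = {"flat": _track({"s": np.ones(5000)}), "ok": self._cov(4, 5000)}
        with pytest.raises(ValueError, match="flat"):
            library_correlation(tracks, [("s", 0, 50000)])
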