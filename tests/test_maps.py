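"""Voxel/region maps, diversity, similarity kernels, UPGMA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from synaptomap import synth
from synaptomap.maps import (diversity_map, dominant_subtype_map,
                             gradient_profile, region_stats,
                             similarity_matrix, upgma_dendrogram, voxelize)


def puncta_table(x_nm, y_nm, **cols):
    df = pd.DataFrame(dict(x_nm=np.asarray(x_nm, float),
                           y_nm=np.asarray(y_nm, float)))
    for k, v in cols.items():
        df[k] = v
    return df


class TestVoxelize:
    def test_single_punctum_density(self):
        vm = voxelize(puncta_table([5000.0], [5000.0]))
        # one punctum in a 19.2 um voxel: 1/368.64 um^2 = 0.271 per 100 um^2
        assert vm.density_per_100um2()[0, 0] == pytest.approx(100 / 368.64)
        assert vm.counts.sum() == 1

    def test_mass_conservation_and_overflow(self):
        rng = np.random.default_rng(0)
        tab = puncta_table(rng.uniform(0, 96000, 500), rng.uniform(0, 96000, 500))
        vm = voxelize(tab, shape=(5, 5))
        assert vm.counts.sum() + vm.overflow == 500

    def test_half_open_binning(self):
        v_nm = 19200.0
        tab = puncta_table([v_nm, v_nm - 1e-9], [0.0, 0.0])
        vm = voxelize(tab, shape=(1, 3))
        assert vm.counts[0, 0] == 1 and vm.counts[0, 1] == 1

    def test_uniform_puncta_poisson_dispersion(self):
        rng = np.random.default_rng(1)
        n, grid = 4000, 10
        span = grid * 19200.0
        tab = puncta_table(rng.uniform(0, span, n), rng.uniform(0, span, n))
        vm = voxelize(tab, shape=(grid, grid))
        counts = vm.counts.ravel()
        # chi-square index of dispersion for Poisson counts
        disp = counts.var(ddof=1) / counts.mean() * (len(counts) - 1)
        lo = stats.chi2.ppf(0.001, len(counts) - 1)
        hi = stats.chi2.ppf(0.999, len(counts) - 1)
        assert lo < disp < hi

    def test_empty_table_zero_map(self):
        vm = voxelize(puncta_table([], []), shape=(3, 3))
        assert vm.counts.sum() == 0

    def test_parameter_means(self):
        tab = puncta_table([100.0, 200.0], [100.0, 200.0],
                           intensity=[10.0, 30.0])
        vm = voxelize(tab, shape=(1, 1))
        assert vm.param_means["intensity"][0, 0] == pytest.approx(20.0)


class TestRegionStats:
    def test_density_50_puncta_in_10000_um2(self):
        # one region of 10,000 um^2 = 100x100 px at 1 um pixels
        atlas = synth.synth_atlas((100, 100),
                                  [dict(region=1, parent="A", rect=(0, 100, 0, 100))],
                                  pixel_size_nm=(1000.0, 1000.0))
        rng = np.random.default_rng(2)
        tab = puncta_table(rng.uniform(0, 1e5, 50), rng.uniform(0, 1e5, 50))
        sig = region_stats(tab, atlas)
        assert sig.density.iloc[0] == pytest.approx(0.5)

    def test_planted_density_ratio(self):
        atlas = synth.synth_atlas((100, 200), [
            dict(region=1, parent="A", rect=(0, 100, 0, 100)),
            dict(region=2, parent="A", rect=(0, 100, 100, 200))],
            pixel_size_nm=(1000.0, 1000.0))
        rng = np.random.default_rng(3)
        x1 = rng.uniform(0, 1e5, 2000)
        x2 = rng.uniform(1e5, 2e5, 1000)
        tab = puncta_table(np.r_[x1, x2], rng.uniform(0, 1e5, 3000))
        sig = region_stats(tab, atlas)
        ratio = sig.density.iloc[0] / sig.density.iloc[1]
        assert ratio == pytest.approx(2.0, rel=0.15)

    def test_single_region_equals_whole_table(self):
        atlas = synth.synth_atlas((10, 10),
                                  [dict(region=1, parent="A", rect=(0, 10, 0, 10))],
                                  pixel_size_nm=(1000.0, 1000.0))
        tab = puncta_table([1000.0, 5000.0], [1000.0, 5000.0],
                           intensity=[5.0, 15.0])
        sig = region_stats(tab, atlas, aggregator="mean")
        assert sig.intensity.iloc[0] == pytest.approx(10.0)
        assert sig.n.iloc[0] == 2

    def test_empty_region_density_zero_params_null(self):
        atlas = synth.synth_atlas((10, 20), [
            dict(region=1, parent="A", rect=(0, 10, 0, 10)),
            dict(region=2, parent="A", rect=(0, 10, 10, 20))],
            pixel_size_nm=(1000.0, 1000.0))
        tab = puncta_table([1000.0], [1000.0], intensity=[4.0])
        sig = region_stats(tab, atlas)
        r2 = sig[sig.region == 2].iloc[0]
        assert r2.density == 0.0 and np.isnan(r2.intensity)


class TestDiversity:
    def test_uniform_37_subtypes_max_entropy(self):
        assert diversity_map(np.ones((37, 1, 1)))[0, 0] == pytest.approx(1.0)

    def test_single_subtype_zero(self):
        d = np.zeros((37, 1, 1))
        d[4] = 3.0
        assert diversity_map(d)[0, 0] == pytest.approx(0.0)

    def test_two_equal_subtypes_closed_form(self):
        d = np.zeros((37, 1, 1))
        d[0] = d[1] = 1.0
        assert diversity_map(d)[0, 0] == pytest.approx(
            np.log2(2) / np.log2(37))

    def test_bounds_and_empty_voxel(self):
        rng = np.random.default_rng(4)
        dens = rng.uniform(0, 5, (37, 6, 6))
        dens[:, 0, 0] = 0.0
        h = diversity_map(dens)
        assert np.isnan(h[0, 0])
        ok = ~np.isnan(h)
        assert (h[ok] >= 0).all() and (h[ok] <= 1.0 + 1e-12).all()

    def test_mixing_two_voxels_never_below_min_entropy(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a = rng.uniform(0, 1, (37, 1, 1))
            b = rng.uniform(0, 1, (37, 1, 1))
            ha = diversity_map(a)[0, 0]
            hb = diversity_map(b)[0, 0]
            hm = diversity_map((a + b) / 2)[0, 0]
            assert hm >= min(ha, hb) - 1e-9

    def test_negative_density_fails(self):
        with pytest.raises(ValueError):
            diversity_map(-np.ones((37, 1, 1)))


class TestDominantSubtype:
    def test_argmax_and_tie_rule(self):
        d = np.zeros((10, 1, 2))
        d[1, 0, 0] = 5.0
        d[2, 0, 0] = 3.0
        d[3, 0, 1] = 2.0   # tie between subtype ids 4 and 9
        d[8, 0, 1] = 2.0
        out = dominant_subtype_map(d)
        assert out[0, 0] == 2
        assert out[0, 1] == 4

    def test_empty_voxel_zero(self):
        assert dominant_subtype_map(np.zeros((5, 1, 1)))[0, 0] == 0

    def test_planted_stripes_reproduced(self):
        dens = np.zeros((3, 4, 6))
        for col in range(6):
            dens[col % 3, :, col] = 1.0
        out = dominant_subtype_map(dens)
        expect = np.tile(np.array([1, 2, 3, 1, 2, 3]), (4, 1))
        np.testing.assert_array_equal(out, expect)


class TestSimilarity:
    def sigs(self, rows):
        df = pd.DataFrame(rows, columns=["density", "intensity"], dtype=float)
        df.insert(0, "region", range(1, len(rows) + 1))
        return df

    def test_identical_signatures_similarity_one(self):
        S, ids, _ = similarity_matrix(self.sigs([[1, 2], [1, 2], [5, 6]]))
        assert S[0, 1] == pytest.approx(1.0)

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(6)
        S, _, _ = similarity_matrix(self.sigs(rng.uniform(0, 1, (6, 2))))
        np.testing.assert_allclose(S, S.T)
        np.testing.assert_allclose(np.diag(S), 1.0)
        assert S.min() >= 0 and S.max() <= 1

    def test_hand_computed_kernel(self):
        # three regions, hand z-score + Gaussian kernel with sigma = median d
        sig = self.sigs([[0, 0], [1, 1], [2, 4]])
        F = sig[["density", "intensity"]].to_numpy()
        Z = (F - F.mean(0)) / F.std(0)
        d01 = np.linalg.norm(Z[0] - Z[1])
        d02 = np.linalg.norm(Z[0] - Z[2])
        d12 = np.linalg.norm(Z[1] - Z[2])
        sigma = np.median([d01, d02, d12])
        S, _, info = similarity_matrix(sig)
        assert info["bandwidth"] == pytest.approx(sigma)
        assert S[0, 1] == pytest.approx(np.exp(-d01**2 / (2 * sigma**2)), abs=1e-12)
        assert S[0, 2] == pytest.approx(np.exp(-d02**2 / (2 * sigma**2)), abs=1e-12)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(7)
        raw = rng.uniform(0, 1, (5, 2))
        s1, _, _ = similarity_matrix(self.sigs(raw))
        scaled = raw.copy()
        scaled[:, 0] = raw[:, 0] * 40.0 - 7.0
        s2, _, _ = similarity_matrix(self.sigs(scaled))
        np.testing.assert_allclose(s1, s2, atol=1e-12)

    def test_constant_column_dropped_with_warning(self):
        sig = self.sigs([[1, 5], [2, 5], [3, 5]])
        S, _, info = similarity_matrix(sig)
        assert info["dropped"] == ["intensity"]
        assert np.isfinite(S).all()

    def test_subtype_pearson_rescaled(self):
        df = pd.DataFrame(np.random.default_rng(8).uniform(0, 1, (4, 37)))
        df.columns = [f"s{i}" for i in range(37)]
        df.insert(0, "region", range(4))
        S, _, info = similarity_matrix(df, method="subtype_pearson",
                                       feature_cols=[f"s{i}" for i in range(37)])
        assert S.min() >= 0 and S.max() <= 1
        np.testing.assert_allclose(S, (info["raw_pearson"] + 1) / 2)


class TestUPGMA:
    def test_two_regions_single_join(self):
        S = np.array([[1.0, 0.4], [0.4, 1.0]])
        tree, Z = upgma_dendrogram(S, ["a", "b"])
        assert Z[0, 2] == pytest.approx(0.6)
        assert {t.name for t in tree.tips()} == {"a", "b"}

    def test_hand_executed_four_leaf_upgma(self):
        # distances: d(a,b)=0.2, d(c,d)=0.3, cross = 0.8
        D = np.array([
            [0.0, 0.2, 0.8, 0.8],
            [0.2, 0.0, 0.8, 0.8],
            [0.8, 0.8, 0.0, 0.3],
            [0.8, 0.8, 0.3, 0.0]])
        S = 1.0 - D
        tree, Z = upgma_dendrogram(S, list("abcd"))
        heights = sorted(Z[:, 2])
        assert heights == pytest.approx([0.2, 0.3, 0.8])
        # planted topology: (a,b) vs (c,d)
        ab = tree.lca([tree.find("a"), tree.find("b")])
        assert {t.name for t in ab.tips()} == {"a", "b"}

    def test_ultrametric_recovery_and_monotone_heights(self):
        # ultrametric with distinct merge heights: ((0,1),2) vs ((3,4),5)
        D = np.full((6, 6), 0.9)
        np.fill_diagonal(D, 0.0)
        D[0, 1] = D[1, 0] = 0.1
        D[0, 2] = D[2, 0] = D[1, 2] = D[2, 1] = 0.3
        D[3, 4] = D[4, 3] = 0.15
        D[3, 5] = D[5, 3] = D[4, 5] = D[5, 4] = 0.35
        tree, Z = upgma_dendrogram(1 - D, [str(i) for i in range(6)])
        assert (np.diff(Z[:, 2]) >= -1e-12).all()
        pair = tree.lca([tree.find("0"), tree.find("1")])
        assert {t.name for t in pair.tips()} == {"0", "1"}
        clade = tree.lca([tree.find("0"), tree.find("2")])
        assert {t.name for t in clade.tips()} == {"0", "1", "2"}
        np.testing.assert_allclose(sorted(Z[:, 2]), [0.1, 0.15, 0.3, 0.35, 0.9])


class TestGradient:
    def test_profile_recovers_monotone_gradient(self):
        rng = np.random.default_rng(10)
        x = rng.uniform(0, 10000, 5000)
        tab = puncta_table(x, rng.uniform(0, 100, 5000),
                           intensity=x / 1000.0 + rng.normal(0, 0.01, 5000))
        prof = gradient_profile(tab, axis="x_nm", n_bins=10)
        assert len(prof) == 10
        assert (np.diff(prof["intensity"]) > 0).all()
        assert prof["n"].sum() == 5000
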