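import numpy as np
import pytest

from t2asym.features import (
    default_registry,
    extract_all,
    region_volume,
    signal_features,
    texture_features,
)
from t2asym.io import grid_affine
from t2asym.phantom import PhantomSpec, build_atlas_geometry
from t2asym.t2map import T2Map

from oracles import oracle_mass_scatter, oracle_signal_features


class TestRegistry:
    def test_family_counts(self):
        reg = default_registry()
        counts = {f: sum(d.family == f for d in reg) for f in ("volume", "signal", "texture")}
        assert counts == {"volume": 1, "signal": 28, "texture": 9}
        assert len(reg) == 38

    def test_names_unique(self):
        names = [d.name for d in default_registry()]
        assert len(names) == len(set(names))


class TestSignalFeatures:
    def test_constant_region_degenerate_values(self):
        f = signal_features([42.0] * 50)
        assert f["sd"] == 0 and f["icv"] == 0
        assert f["entropy"] == 0 and f["energy"] == 1
        assert all(f[f"value_at_{lv:g}"] == 42.0 for lv in (0.01, 1, 5, 25, 50, 75, 95, 99, 99.99))
        assert f["p_below_2sd"] == f["p_above_3sd"] == 0

    def test_symmetric_sample_has_zero_skewness(self):
        v = np.concatenate([100 - np.arange(1, 30), [100.0], 100 + np.arange(1, 30)])
        assert abs(signal_features(v)["skewness"]) < 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.uniform(20, 200, size=rng.integers(30, 400))
        got = signal_features(v)
        want = oracle_signal_features(v)
        assert set(got) == set(want)
        for k in want:
            assert got[k] == pytest.approx(want[k], abs=1e-9, rel=1e-9), k

    def test_one_to_hundred_against_oracle(self):
        v = np.arange(1.0, 101.0)
        got = signal_features(v)
        want = oracle_signal_features(v)
        for k in want:
            assert got[k] == pytest.approx(want[k], abs=1e-9, rel=1e-9), k

    def test_intensity_scaling_behavior(self):
        rng = np.random.default_rng(8)
        v = rng.uniform(50, 150, 200)
        base = signal_features(v)
        scaled = signal_features(3.0 * v)
        scale_with_k = ["mean", "sd", "precision_range", "mad", "min", "max", "range",
                        "mean_c90", "sd_c90"] + [f"value_at_{lv:g}" for lv in
                        (0.01, 1, 5, 25, 50, 75, 95, 99, 99.99)]
        invariant = ["icv", "icv_c90", "skewness", "kurtosis", "entropy", "energy",
                     "p_below_2sd", "p_below_3sd", "p_above_2sd", "p_above_3sd"]
        for k in scale_with_k:
            assert scaled[k] == pytest.approx(3.0 * base[k], rel=1e-9), k
        for k in invariant:
            assert scaled[k] == pytest.approx(base[k], rel=1e-9, abs=1e-12), k


class TestTextureFeatures:
    def test_single_voxel_point_mass(self):
        f = texture_features(np.array([[3, 4, 5]]), np.array([100.0]), (1.0, 1.0, 1.0))
        for ab in ("xx", "yy", "zz", "xy", "xz", "yz"):
            assert f[f"mass_scatter_{ab}"] == 0.0
        assert f["surface_area"] == 6.0  # 6 unit faces

    def test_two_voxels_4mm_apart_along_y(self):
        idx = np.array([[0, 0, 0], [0, 4, 0]])
        f = texture_features(idx, np.array([1.0, 1.0]), (1.0, 1.0, 1.0))
        assert f["mass_scatter_yy"] == pytest.approx(4.0)
        for ab in ("xx", "zz", "xy", "xz", "yz"):
            assert f[f"mass_scatter_{ab}"] == 0.0

    @pytest.mark.parametrize("seed", range(3))
    def test_tensor_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, 12, size=(60, 3))
        idx = np.unique(idx, axis=0)
        vals = rng.uniform(50, 150, len(idx))
        spacing = (2.0, 1.5, 3.0)
        f = texture_features(idx, vals, spacing)
        m = oracle_mass_scatter(idx.tolist(), vals.tolist(), spacing)
        assert f["mass_scatter_xx"] == pytest.approx(m[0][0], rel=1e-9)
        assert f["mass_scatter_yy"] == pytest.approx(m[1][1], rel=1e-9)
        assert f["mass_scatter_zz"] == pytest.approx(m[2][2], rel=1e-9)
        assert f["mass_scatter_xy"] == pytest.approx(m[0][1], rel=1e-9, abs=1e-12)
        assert f["mass_scatter_xz"] == pytest.approx(m[0][2], rel=1e-9, abs=1e-12)
        assert f["mass_scatter_yz"] == pytest.approx(m[1][2], rel=1e-9, abs=1e-12)

    def test_translation_invariance(self):
        rng = np.random.default_rng(4)
        idx = np.unique(rng.integers(0, 10, size=(40, 3)), axis=0)
        vals = rng.uniform(50, 150, len(idx))
        base = texture_features(idx, vals, (1.0, 1.0, 1.0))
        shifted = texture_features(idx + np.array([7, 11, 13]), vals, (1.0, 1.0, 1.0))
        for k, v in base.items():
            assert shifted[k] == pytest.approx(v, rel=1e-9, abs=1e-12), k

    def test_intensity_scale_cancels_in_weights(self):
        rng = np.random.default_rng(6)
        idx = np.unique(rng.integers(0, 10, size=(40, 3)), axis=0)
        vals = rng.uniform(50, 150, len(idx))
        base = texture_features(idx, vals, (1.0, 1.0, 1.0))
        scaled = texture_features(idx, 5.0 * vals, (1.0, 1.0, 1.0))
        for k, v in base.items():
            assert scaled[k] == pytest.approx(v, rel=1e-9, abs=1e-12), k

    def test_cube_compactness(self):
        # 4x4x4 cube of unit voxels: V=64, A=96, compactness = 36*pi*64^2/96^3
        idx = np.array([(i, j, k) for i in range(4) for j in range(4) for k in range(4)])
        f = texture_features(idx, np.ones(len(idx)), (1.0, 1.0, 1.0))
        assert f["surface_area"] == pytest.approx(96.0)
        assert f["compactness"] == pytest.approx(36 * np.pi * 64**2 / 96**3)
        assert f["sphericity"] == pytest.approx(f["compactness"] ** (1 / 3))


class TestRegionVolume:
    def test_voxel_count_times_voxel_volume(self):
        labels = np.zeros((10, 10, 10), dtype=int)
        labels.flat[:100] = 1
        assert region_volume(labels, 1, (2.0, 2.0, 2.0)) == pytest.approx(800.0)

    def test_absent_label_is_zero(self):
        assert region_volume(np.zeros((4, 4, 4), dtype=int), 9, (1, 1, 1)) == 0.0

    def test_rasterized_ellipsoid_close_to_analytic(self):
        shape = (32, 32, 32)
        x, y, z = np.ogrid[:32, :32, :32]
        mask = ((x - 16) / 8) ** 2 + ((y - 16) / 6) ** 2 + ((z - 16) / 6) ** 2 <= 1
        labels = mask.astype(int)
        vol = region_volume(labels, 1, (1.0, 1.0, 1.0))
        analytic = 4 / 3 * np.pi * 8 * 6 * 6
        assert abs(vol - analytic) / analytic < 0.05


class TestExtractAll:
    @pytest.fixture(scope="class")
    def phantom_map(self):
        spec = PhantomSpec(noise_sd=0.0, s0_sd=0.0)
        labels, atlas = build_atlas_geometry(spec)
        rng = np.random.default_rng(0)
        t2 = np.where(labels > 0, 80.0 + 5.0 * labels + rng.uniform(0, 5, labels.shape), 0.0)
        tmap = T2Map(t2, labels > 0, (1.0, 3000.0), spec.voxel_size_mm, grid_affine(spec.voxel_size_mm))
        return tmap, labels, atlas

    def test_default_registry_yields_38_per_region(self, phantom_map):
        tmap, labels, atlas = phantom_map
        df = extract_all(tmap, labels, atlas)
        per_region = df.groupby("region").size()
        assert (per_region == 38).all()
        assert df.value.notna().all()

    @pytest.mark.parametrize("family,expected", [("signal", 28), ("texture", 9)])
    def test_family_restricted_registry(self, phantom_map, family, expected):
        tmap, labels, atlas = phantom_map
        reg = [d for d in default_registry() if d.family == family]
        df = extract_all(tmap, labels, atlas, registry=reg)
        assert (df.groupby("region").size() == expected).all()

    def test_small_region_degrades_to_missing_not_abort(self, phantom_map):
        tmap, labels, atlas = phantom_map
        # invalidate most of region 1's voxels
        mask = labels == 1
        keep = np.argwhere(mask)[:5]
        valid = tmap.valid_mask.copy()
        valid[mask] = False
        valid[tuple(keep.T)] = True
        small = T2Map(tmap.t2_ms, valid, tmap.clip_range_ms, tmap.spacing_mm, tmap.affine)
        df = extract_all(small, labels, atlas, min_voxels=10)
        r1 = df[df.region == 1]
        assert r1[r1.feature == "volume"].value.notna().all()
        assert r1[r1.family != "volume"].value.isna().all()
        # other regions unaffected
        assert df[df.region == 2].value.notna().all()
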