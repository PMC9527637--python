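"""3D morphometry: closed forms, digital fixtures, density oracle, ANOVA."""
import numpy as np
import pytest
from scipy import stats as sps

from cardiomorph.morpho import (
    compare_distributions,
    density_map,
    label_components,
    mutual_volume_jaccard,
    shape_stats,
    shape_stats_from_measures,
)
from cardiomorph.volumes import LabelVolume


def digital_ball(r, shape=None, spacing=(1.0, 1.0, 1.0)):
    shape = shape or (2 * r + 5,) * 3
    c = [(s - 1) / 2 for s in shape]
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (
        ((zz - c[0]) * spacing[0]) ** 2
        + ((yy - c[1]) * spacing[1]) ** 2
        + ((xx - c[2]) * spacing[2]) ** 2
    ) <= r**2


def digital_ellipsoid(a, b, c):
    shape = (2 * a + 5, 2 * b + 5, 2 * c + 5)
    cc = [(s - 1) / 2 for s in shape]
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return ((zz - cc[0]) / a) ** 2 + ((yy - cc[1]) / b) ** 2 + ((xx - cc[2]) / c) ** 2 <= 1.0


class TestLabelComponents:
    def test_two_disjoint_cubes(self):
        vol = np.zeros((10, 10, 10), dtype=np.uint8)
        vol[1:4, 1:4, 1:4] = 1
        vol[6:9, 6:9, 6:9] = 1
        _, n = label_components(LabelVolume(vol), class_id=1)
        assert n == 2

    def test_corner_touch_connectivity(self):
        vol = np.zeros((6, 6, 6), dtype=np.uint8)
        vol[1:3, 1:3, 1:3] = 1
        vol[3:5, 3:5, 3:5] = 1  # touch at one corner voxel pair
        _, n26 = label_components(LabelVolume(vol), 1, connectivity=26)
        _, n6 = label_components(LabelVolume(vol), 1, connectivity=6)
        assert n26 == 1 and n6 == 2

    def test_empty_mask(self):
        _, n = label_components(LabelVolume(np.zeros((4, 4, 4), dtype=np.uint8)), 1)
        assert n == 0

    def test_invalid_connectivity(self):
        with pytest.raises(ValueError):
            label_components(LabelVolume(np.zeros((4, 4, 4), dtype=np.uint8)), 1, connectivity=18)


class TestShapeClosedForms:
    def test_exact_sphere_measures(self):
        r = 3.0
        m = shape_stats_from_measures(V=4 / 3 * np.pi * r**3, S=4 * np.pi * r**2)
        assert m["compactness"] == pytest.approx(1.0)
        assert m["sphericity"] == pytest.approx(1.0)
        assert m["sa_to_v"] == pytest.approx(3 / r)

    def test_exact_cube_measures(self):
        a = 2.0
        m = shape_stats_from_measures(V=a**3, S=6 * a**2)
        assert m["compactness"] == pytest.approx(np.pi / 6)
        assert m["sphericity"] == pytest.approx((np.pi / 6) ** (1 / 3))

    def test_digital_ball_r20(self):
        comp, n = label_components(digital_ball(20), connectivity=26)
        assert n == 1
        row = shape_stats(comp).iloc[0]
        assert 0.95 <= row.sphericity <= 1.0
        assert 1.0 <= row.elongation <= 1.05
        assert 1.0 <= row.flatness <= 1.05
        assert row.sa_to_v == pytest.approx(3 / 20, rel=0.05)

    def test_digital_ellipsoid_axis_ratios(self):
        """Covariance of a solid ellipsoid is diag(a^2, b^2, c^2)/5, so the
        (40, 20, 10) ellipsoid has elongation 2 and flatness 2."""
        comp, n = label_components(digital_ellipsoid(40, 20, 10), connectivity=26)
        assert n == 1
        row = shape_stats(comp).iloc[0]
        assert row.elongation == pytest.approx(2.0, rel=0.05)
        assert row.flatness == pytest.approx(2.0, rel=0.05)
        assert row.spareness == pytest.approx(1.0, rel=0.1)

    def test_sphere_attains_extremes(self):
        """Among ball / cube / ellipsoid, the ball has the highest sphericity
        and the lowest SA:V at comparable volume."""
        ball = digital_ball(16)
        cube = np.zeros((31, 31, 31), dtype=bool)
        a = int(round((ball.sum()) ** (1 / 3)))
        cube[1 : 1 + a, 1 : 1 + a, 1 : 1 + a] = True
        ell = digital_ellipsoid(32, 16, 8)
        rows = {}
        for name, mask in [("ball", ball), ("cube", cube), ("ellipsoid", ell)]:
            comp, _ = label_components(mask)
            rows[name] = shape_stats(comp).iloc[0]
        assert rows["ball"].sphericity == max(r.sphericity for r in rows.values())
        # compare SA:V at matched volume: rescale by (V_shape / V_ball)^(1/3)
        for name in ("cube", "ellipsoid"):
            scale = (rows[name].volume_um3 / rows["ball"].volume_um3) ** (1 / 3)
            assert rows["ball"].sa_to_v < rows[name].sa_to_v * scale * 1.001

    def test_sa_to_v_scale_law(self):
        rows = {}
        for r in (10, 20):
            comp, _ = label_components(digital_ball(r))
            rows[r] = shape_stats(comp).iloc[0].sa_to_v
        assert rows[10] / rows[20] == pytest.approx(2.0, rel=0.05)

    def test_voxel_face_estimator_biased_high_on_ball(self):
        comp, _ = label_components(digital_ball(15))
        mesh = shape_stats(comp, surface_estimator="mesh").iloc[0].surface_um2
        faces = shape_stats(comp, surface_estimator="voxel_faces").iloc[0].surface_um2
        assert 1.3 <= faces / mesh <= 1.7

    def test_anisotropic_voxels_scale_moments(self):
        """A ball sampled on a 2x1x1 grid has isotropic physical moments."""
        mask = digital_ball(12, shape=(18, 30, 30), spacing=(2.0, 1.0, 1.0))
        comp, _ = label_components(mask)
        row = shape_stats(comp, voxel_size_um=(2.0, 1.0, 1.0)).iloc[0]
        assert row.elongation == pytest.approx(1.0, abs=0.1)
        assert row.flatness == pytest.approx(1.0, abs=0.1)

    def test_tiny_component_flagged_unreliable(self):
        vol = np.zeros((6, 6, 6), dtype=np.uint8)
        vol[2, 2, 2:4] = 1
        comp, _ = label_components(LabelVolume(vol), 1)
        df = shape_stats(comp)
        assert not df.iloc[0].reliable

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            shape_stats(np.zeros((4, 4, 4), dtype=int))


class TestDensityMap:
    def test_uniform_interleave_constant_half(self):
        """1 part mitochondria : 2 parts myofibril, uniformly -> every cell 0.5."""
        pattern = np.array([1, 2, 2], dtype=np.uint8)
        data = np.tile(pattern, (12, 12, 4))
        vol = LabelVolume(data, (1.0, 1.0, 1.0))
        dm = density_map(vol, kernel_um=6.0, stride_um=3.0)
        assert dm.n_undefined == 0
        assert np.allclose(dm.values, 0.5)

    def test_no_mitochondria_all_zero(self):
        data = np.full((8, 8, 8), 2, dtype=np.uint8)
        dm = density_map(LabelVolume(data), kernel_um=4.0, stride_um=2.0)
        assert np.all(dm.values == 0.0)

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(0)
        data = rng.integers(0, 4, (14, 15, 16)).astype(np.uint8)
        vol = LabelVolume(data, (0.5, 0.5, 0.5))
        dm = density_map(vol, kernel_um=3.0, stride_um=1.0)
        k = 6  # 3.0 um / 0.5 um
        s = 2  # 1.0 um / 0.5 um
        expected = np.full_like(dm.values, np.nan)
        nz, ny, nx = data.shape
        for iz, z in enumerate(range(0, nz - k + 1, s)):
            for iy, y in enumerate(range(0, ny - k + 1, s)):
                for ix, x in enumerate(range(0, nx - k + 1, s)):
                    w = data[z : z + k, y : y + k, x : x + k]
                    mito = np.count_nonzero(w == 1)
                    myo = np.count_nonzero(w == 2)
                    if myo:
                        expected[iz, iy, ix] = mito / myo
        assert dm.values.shape == expected.shape
        assert np.allclose(dm.values, expected, equal_nan=True)

    def test_undefined_windows_counted(self):
        data = np.zeros((6, 6, 6), dtype=np.uint8)
        data[0, 0, 0] = 1
        dm = density_map(LabelVolume(data), kernel_um=3.0, stride_um=3.0)
        assert dm.n_undefined == dm.values.size
        assert np.all(np.isnan(dm.values))

    def test_kernel_too_large(self):
        with pytest.raises(ValueError):
            density_map(LabelVolume(np.zeros((4, 4, 4), dtype=np.uint8)), kernel_um=10.0)


class TestCompareDistributions:
    def test_identical_samples(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        rep = compare_distributions(a, a.copy())
        assert rep.f_means == pytest.approx(0.0)
        assert rep.p_means == pytest.approx(1.0)

    def test_hand_computed_anova_table(self):
        """3+3 toy: groups (1,2,3) and (2,3,4); SSB=1.5, SSW=4, F=1.5."""
        a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        rep = compare_distributions(a, b)
        assert rep.f_means == pytest.approx(1.5)
        assert rep.p_means == pytest.approx(1 - sps.f.cdf(1.5, 1, 4))

    def test_large_shift_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 50)
        rep = compare_distributions(a, a + 10)
        assert rep.p_means < 0.001

    def test_zero_variance_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            rep = compare_distributions([2.0, 2.0, 2.0], [2.0, 2.0])
        assert rep.degenerate

    def test_variance_ratio_test(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 80)
        b = rng.normal(0, 5, 80)
        rep = compare_distributions(a, b)
        assert rep.p_var < 0.001

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            compare_distributions([1.0], [2.0, 3.0])


class TestMutualVolumeJaccard:
    def test_copies_zero_matrix(self):
        v = LabelVolume(np.random.default_rng(0).integers(0, 4, (4, 8, 8)).astype(np.uint8))
        d = mutual_volume_jaccard([v, v, v])
        assert np.all(d == 0.0)

    def test_disjoint_pair(self):
        a = np.zeros((4, 4, 4), dtype=np.uint8)
        b = np.zeros((4, 4, 4), dtype=np.uint8)
        a[0] = 1
        b[1] = 1
        d = mutual_volume_jaccard([LabelVolume(a), LabelVolume(b)])
        assert d[0, 1] == 1.0 and d[1, 0] == 1.0 and d[0, 0] == 0.0

    def test_consistent_with_direct_calls(self):
        from cardiomorph.assembly import jaccard_distance

        rng = np.random.default_rng(3)
        vols = [
            LabelVolume(rng.integers(0, 4, (4, 8, 8)).astype(np.uint8)) for _ in range(3)
        ]
        d = mutual_volume_jaccard(vols)
        for i in range(3):
            for j in range(3):
                assert d[i, j] == pytest.approx(
                    jaccard_distance(vols[i], vols[j]) if i != j else 0.0
                )

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            mutual_volume_jaccard(
                [
                    LabelVolume(np.zeros((2, 2, 2), dtype=np.uint8)),
                    LabelVolume(np.zeros((3, 3, 3), dtype=np.uint8)),
                ]
            )
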