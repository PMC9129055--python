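"""Activity measures: spectral amplitudes, Kendall's W, homotopic correlation."""

import numpy as np
import pytest
from scipy import stats

from rsfusion import (
    BandSpec,
    BrainMask,
    compute_alff,
    compute_falff,
    compute_reho,
    compute_vmhc,
    standardize_map,
)

from conftest import make_volume, volume_from_series


def kendall_w_bruteforce(series_list):
    """Explicit rank-sum Kendall's W: independent oracle for ReHo.

    Ranks each series over time (average ranks for ties), sums ranks per
    timepoint and evaluates W = 12 S / (K^2 (T^3 - T)).
    """
    K = len(series_list)
    T = len(series_list[0])
    ranks = np.array([stats.rankdata(s) for s in series_list])
    rank_sums = ranks.sum(axis=0)
    mean_rank_sum = K * (T + 1) / 2.0
    s = float(((rank_sums - mean_rank_sum) ** 2).sum())
    return 12.0 * s / (K**2 * (T**3 - T))


def reho_instance(series_by_voxel, grid=(3, 3, 3)):
    """Build a volume + mask holding the given center-neighbourhood series."""
    T = len(next(iter(series_by_voxel.values())))
    data = np.zeros((*grid, T))
    mask = np.zeros(grid, dtype=bool)
    for voxel, series in series_by_voxel.items():
        data[voxel] = series
        mask[voxel] = True
    return make_volume(data), BrainMask(mask)


class TestReho:
    def test_identical_series_give_w_one(self, rng):
        series = rng.normal(size=20)
        vol = volume_from_series(series, grid=(3, 3, 3))
        mask = BrainMask(np.ones((3, 3, 3), dtype=bool))
        out = compute_reho(vol, mask)
        assert out.data[1, 1, 1] == pytest.approx(1.0, abs=1e-12)

    def test_hand_example_k3_t4(self):
        series = {(0, 0, 0): [1, 2, 3, 4], (1, 0, 0): [2, 1, 4, 3], (2, 0, 0): [1, 3, 2, 4]}
        vol, mask = reho_instance(series, grid=(3, 1, 1))
        out = compute_reho(vol, mask)
        expected = kendall_w_bruteforce(list(series.values()))
        assert out.data[1, 0, 0] == pytest.approx(expected, abs=1e-12)

    def test_matches_bruteforce_on_random_neighbourhoods(self, rng):
        """compute_reho equals the explicit rank-sum W on random masked
        3x3x3 neighbourhoods with K <= 27, T <= 30."""
        for _ in range(100):
            T = int(rng.integers(4, 31))
            mask = rng.random((3, 3, 3)) > 0.4
            mask[1, 1, 1] = True
            series = {
                tuple(v): rng.normal(size=T) for v in np.argwhere(mask)
            }
            vol, bmask = reho_instance(series)
            out = compute_reho(vol, bmask)
            if len(series) >= 2:
                expected = kendall_w_bruteforce(list(series.values()))
                assert abs(out.data[1, 1, 1] - expected) < 1e-10
            else:
                assert out.data[1, 1, 1] == 0.0
                assert out.flags[1, 1, 1]

    def test_null_mean_is_one_over_k(self, rng):
        # E[W] = 1/K for independent rankings; interior voxels have K = 27.
        vol = make_volume(rng.normal(size=(14, 14, 14, 20)))
        mask = BrainMask(np.ones((14, 14, 14), dtype=bool))
        out = compute_reho(vol, mask)
        interior = out.data[1:-1, 1:-1, 1:-1]  # 1728 voxels with K=27
        assert interior.mean() == pytest.approx(1 / 27, rel=0.1)

    def test_values_in_unit_interval(self, rng):
        for _ in range(20):
            vol = make_volume(rng.normal(size=(6, 6, 6, 12)))
            mask = BrainMask(rng.random((6, 6, 6)) > 0.3)
            out = compute_reho(vol, mask)
            vals = out.data[mask.data]
            assert np.all((vals >= 0) & (vals <= 1 + 1e-12))

    def test_isolated_voxel_flagged_zero(self, rng):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[0, 0, 0] = True
        mask[4, 4, 4] = True
        vol = make_volume(rng.normal(size=(5, 5, 5, 10)))
        out = compute_reho(vol, BrainMask(mask))
        assert out.data[0, 0, 0] == 0.0
        assert out.flags[0, 0, 0]


from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays


@settings(deadline=None, derandomize=True, max_examples=30)
@given(
    data=arrays(np.float64, (3, 3, 3, 8),
                elements=st.floats(-50, 50, allow_nan=False)),
)
def test_reho_always_in_unit_interval(data):
    vol = make_volume(data)
    mask = BrainMask(np.ones((3, 3, 3), dtype=bool))
    out = compute_reho(vol, mask)
    vals = out.data[mask.data]
    assert np.all((vals >= -1e-12) & (vals <= 1 + 1e-9))


class TestAlff:
    mask = BrainMask(np.ones((4, 4, 4), dtype=bool))

    def test_zero_series_zero_alff(self):
        vol = make_volume(np.zeros((4, 4, 4, 64)))
        assert np.all(compute_alff(vol, self.mask).data == 0)

    def test_bin_aligned_sine_matches_fft_oracle(self):
        T, tr = 200, 2.0
        t = np.arange(T) * tr
        series = np.sin(2 * np.pi * 0.05 * t)
        vol = volume_from_series(series)
        out = compute_alff(vol, self.mask)
        freqs = np.fft.rfftfreq(T, d=tr)
        amp = 2.0 * np.abs(np.fft.rfft(series)) / T
        in_band = (freqs >= 0.01 - 1e-12) & (freqs <= 0.1 + 1e-12)
        expected = amp[in_band].mean()  # one unit-amplitude bin / 37 bins
        assert out.data[0, 0, 0] == pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(1.0 / in_band.sum(), abs=1e-10)

    def test_linearity_in_amplitude(self, rng):
        vol = make_volume(rng.normal(size=(4, 4, 4, 64)))
        doubled = make_volume(2.0 * vol.data)
        a1 = compute_alff(vol, self.mask).data
        a2 = compute_alff(doubled, self.mask).data
        assert np.allclose(a2, 2.0 * a1, atol=1e-12)

    def test_too_few_inband_bins_raises(self):
        vol = make_volume(np.zeros((4, 4, 4, 16)), tr=0.1)  # df=0.625 Hz
        with pytest.raises(ValueError):
            compute_alff(vol, self.mask, BandSpec(0.01, 0.1))


class TestFalff:
    mask = BrainMask(np.ones((4, 4, 4), dtype=bool))

    def test_pure_inband_tone_gives_one(self):
        t = np.arange(200) * 2.0
        vol = volume_from_series(np.sin(2 * np.pi * 0.05 * t))
        out = compute_falff(vol, self.mask)
        assert out.data[0, 0, 0] == pytest.approx(1.0, abs=1e-10)

    def test_pure_outband_tone_gives_zero(self):
        t = np.arange(200) * 2.0
        vol = volume_from_series(np.sin(2 * np.pi * 0.2 * t))
        out = compute_falff(vol, self.mask)
        assert out.data[0, 0, 0] < 1e-10

    def test_white_noise_mean_matches_bin_ratio(self, rng):
        T, tr = 200, 2.0
        data = rng.normal(size=(10, 10, 10, T))  # 1000 voxels
        vol = make_volume(data, tr=tr)
        mask = BrainMask(np.ones((10, 10, 10), dtype=bool))
        out = compute_falff(vol, mask)
        freqs = np.fft.rfftfreq(T, d=tr)
        ratio = ((freqs >= 0.01) & (freqs <= 0.1)).sum() / (freqs > 0).sum()
        assert out.data.mean() == pytest.approx(ratio, rel=0.05)

    def test_constant_series_zero_by_convention(self):
        vol = make_volume(np.zeros((4, 4, 4, 64)))
        assert np.all(compute_falff(vol, self.mask).data == 0)


class TestVmhc:
    def test_identical_mirrored_series_clipped_finite(self, rng):
        series = rng.normal(size=50)
        vol = volume_from_series(series, grid=(4, 4, 4))
        mask = BrainMask(np.ones((4, 4, 4), dtype=bool))
        out = compute_vmhc(vol, mask)
        expected = np.arctanh(1.0 - 1e-7)
        assert out.data[0, 0, 0] == pytest.approx(expected, abs=1e-9)
        assert np.all(np.isfinite(out.data))

    def test_sign_flipped_series_antisymmetric(self, rng):
        series = rng.normal(size=50)
        data = np.zeros((4, 1, 1, 50))
        data[0, 0, 0] = series
        data[3, 0, 0] = -series
        data[1, 0, 0] = series
        data[2, 0, 0] = -series
        vol = make_volume(data)
        mask = BrainMask(np.ones((4, 1, 1), dtype=bool))
        out = compute_vmhc(vol, mask)
        assert out.data[0, 0, 0] == pytest.approx(np.arctanh(-1 + 1e-7), abs=1e-9)

    def test_null_mean_near_zero(self, rng):
        # Fisher z has null variance ~ 1/(T-3).
        T = 120
        vol = make_volume(rng.normal(size=(10, 20, 20, T)))
        mask = BrainMask(np.ones((10, 20, 20), dtype=bool))
        out = compute_vmhc(vol, mask)
        vals = out.data[mask.data]
        n_pairs = 2000  # 4000 voxels in 2000 mirrored pairs
        assert abs(vals.mean()) < 2.0 / np.sqrt(n_pairs * (T - 3))

    def test_mirror_symmetry(self, rng):
        vol = make_volume(rng.normal(size=(6, 5, 5, 30)))
        mask = BrainMask(np.ones((6, 5, 5), dtype=bool))
        out = compute_vmhc(vol, mask)
        assert np.allclose(out.data, out.data[::-1], atol=1e-12)

    def test_self_mirrored_and_unpaired_flagged(self, rng):
        mask_arr = np.ones((5, 4, 4), dtype=bool)
        mask_arr[0, 0, 0] = False  # unpaired: (4,0,0) has no in-mask mirror
        vol = make_volume(rng.normal(size=(5, 4, 4, 20)))
        out = compute_vmhc(vol, BrainMask(mask_arr))
        assert out.data[2, 1, 1] == 0.0 and out.flags[2, 1, 1]  # midline plane
        assert out.data[4, 0, 0] == 0.0 and out.flags[4, 0, 0]

    def test_zero_variance_series_flagged(self, rng):
        data = rng.normal(size=(4, 4, 4, 20))
        data[0, 0, 0] = 5.0  # constant series
        vol = make_volume(data)
        mask = BrainMask(np.ones((4, 4, 4), dtype=bool))
        out = compute_vmhc(vol, mask)
        assert out.data[0, 0, 0] == 0.0
        assert out.flags[0, 0, 0]


class TestStandardize:
    def test_mean_zero_sd_one(self, rng):
        from rsfusion import ActivityMap

        mask = BrainMask(rng.random((5, 5, 5)) > 0.3)
        data = rng.normal(2.0, 3.0, size=(5, 5, 5))
        amap = ActivityMap(data, "alff", mask)
        out = standardize_map(amap)
        vals = out.data[mask.data]
        assert abs(vals.mean()) < 1e-10
        assert vals.std() == pytest.approx(1.0, abs=1e-10)
        assert out.standardized

    def test_affine_invariance(self, rng):
        from rsfusion import ActivityMap

        mask = BrainMask(np.ones((4, 4, 4), dtype=bool))
        data = rng.normal(size=(4, 4, 4))
        a = standardize_map(ActivityMap(data, "reho", mask))
        b = standardize_map(ActivityMap(2.5 * data + 7.0, "reho", mask))
        assert np.allclose(a.data, b.data, atol=1e-10)

    def test_two_voxel_population_sd_convention(self):
        from rsfusion import ActivityMap

        mask_arr = np.zeros((4, 4, 4), dtype=bool)
        mask_arr[0, 0, 0] = mask_arr[1, 0, 0] = True
        data = np.zeros((4, 4, 4))
        data[0, 0, 0], data[1, 0, 0] = 1.0, 3.0
        out = standardize_map(ActivityMap(data, "alff", BrainMask(mask_arr)))
        assert out.data[0, 0, 0] == pytest.approx(-1.0)
        assert out.data[1, 0, 0] == pytest.approx(1.0)

    def test_zero_variance_raises(self):
        from rsfusion import ActivityMap

        mask = BrainMask(np.ones((4, 4, 4), dtype=bool))
        with pytest.raises(ValueError):
            standardize_map(ActivityMap(np.ones((4, 4, 4)), "alff", mask))
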