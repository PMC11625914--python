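"""Unit and oracle tests for the resting-state feature maps."""
import numpy as np
import pytest
from scipy import stats

from nvcoupling.features import (bandpass, compute_alff, compute_dc,
                                 compute_reho, kendall_w, nuisance_design,
                                 nuisance_regress, smooth_gaussian, zscore_map)
from nvcoupling.types import (BoldSeries, DegeneracyError, FeatureMap,
                              MotionParams, TissueMasks)

from conftest import make_series


def sinusoid_series(freq_hz, t=240, tr=1.5, amplitude=1.0):
    time = np.arange(t) * tr
    x = amplitude * np.sin(2 * np.pi * freq_hz * time)
    return make_series(x.reshape(1, 1, 1, t), tr_s=tr)


class TestBandpass:
    def test_constant_series_maps_to_zero(self):
        s = make_series(np.full((2, 2, 1, 80), 7.0))
        assert np.allclose(bandpass(s).values, 0.0, atol=1e-12)

    @pytest.mark.parametrize("freq,lo,hi", [(0.05, 0.95, None), (0.25, None, 0.10)])
    def test_passband_and_stopband_amplitude(self, freq, lo, hi):
        s = sinusoid_series(freq)
        out = bandpass(s)
        ratio = out.values.std() / s.values.std()
        if lo is not None:
            assert ratio >= lo
        if hi is not None:
            assert ratio <= hi

    def test_matches_fft_oracle_per_bin(self, rng):
        x = rng.standard_normal((1, 1, 1, 128))
        s = make_series(x, tr_s=1.5)
        out = bandpass(s, 0.01, 0.1)
        freqs = np.fft.rfftfreq(128, 1.5)
        spec_in = np.fft.rfft(x.ravel())
        spec_out = np.fft.rfft(out.values.ravel())
        inband = (freqs >= 0.01 + (freqs[1] - freqs[0])) & \
                 (freqs <= 0.1 - (freqs[1] - freqs[0]))
        far_out = (freqs > 0.1 + 2 * (freqs[1] - freqs[0])) | \
                  ((freqs < 0.01 - 2 * (freqs[1] - freqs[0])) & (freqs > 0))
        assert np.allclose(spec_out[inband], spec_in[inband], atol=1e-9)
        assert np.allclose(spec_out[far_out], 0.0, atol=1e-9)

    def test_high_cutoff_above_nyquist_rejected(self):
        s = sinusoid_series(0.05)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(s, 0.01, 0.4)


def _random_inputs(rng, shape=(4, 4, 3), t=60):
    vals = rng.standard_normal((*shape, t))
    brain = np.ones(shape, dtype=bool)
    wm = np.zeros(shape, dtype=bool)
    wm[0, 0, 0] = True
    csf = np.zeros(shape, dtype=bool)
    csf[-1, -1, -1] = True
    masks = TissueMasks(brain=brain, wm=wm, csf=csf)
    motion = MotionParams(rng.standard_normal((t, 6)))
    return make_series(vals), motion, masks


class TestNuisanceRegression:
    def test_perfect_confound_removed(self, rng):
        series, motion, masks = _random_inputs(rng)
        vals = series.values.copy()
        vals[1, 1, 1, :] = 3.0 * motion.values[:, 0]
        out = nuisance_regress(make_series(vals), motion, masks)
        assert np.allclose(out.values[1, 1, 1], 0.0, atol=1e-8)

    def test_orthogonal_series_only_demeaned(self, rng):
        series, motion, masks = _random_inputs(rng)
        X, _ = nuisance_design(motion, series, masks)
        # build a voxel series orthogonal to all 27 columns
        y = rng.standard_normal(series.n_timepoints)
        y -= X @ np.linalg.lstsq(X, y, rcond=None)[0]
        vals = series.values.copy()
        vals[2, 2, 1, :] = y + 5.0  # constant offset soaked up by intercept
        # keep WM/CSF voxels untouched so the design is identical
        out = nuisance_regress(make_series(vals), motion, masks)
        assert np.allclose(out.values[2, 2, 1], y, atol=1e-8)

    def test_residuals_match_normal_equations_oracle(self, rng):
        series, motion, masks = _random_inputs(rng)
        out = nuisance_regress(series, motion, masks)
        X, _ = nuisance_design(motion, series, masks)
        proj = X @ np.linalg.solve(X.T @ X, X.T)
        t = series.n_timepoints
        flat = series.values.reshape(-1, t).T
        expected = flat - proj @ flat
        assert np.allclose(out.values.reshape(-1, t).T, expected, atol=1e-8)

    def test_residuals_orthogonal_to_design(self, rng):
        series, motion, masks = _random_inputs(rng)
        out = nuisance_regress(series, motion, masks)
        X, _ = nuisance_design(motion, series, masks)
        t = series.n_timepoints
        inner = X.T @ out.values.reshape(-1, t).T
        scale = np.linalg.norm(X, axis=0)[:, None] * \
            np.linalg.norm(series.values.reshape(-1, t).T, axis=0)[None, :]
        assert np.max(np.abs(inner) / scale) < 1e-6

    def test_collinear_columns_named(self, rng):
        series, motion, masks = _random_inputs(rng)
        m = motion.values.copy()
        m[:, 1] = 2.0 * m[:, 0]  # exact collinearity
        with pytest.raises(DegeneracyError, match="trans_y"):
            nuisance_regress(series, MotionParams(m), masks)

    def test_motion_row_mismatch_rejected(self, rng):
        series, motion, masks = _random_inputs(rng)
        with pytest.raises(ValueError, match="motion rows"):
            nuisance_regress(series, MotionParams(motion.values[:-3]), masks)


class TestSmoothing:
    def test_zero_fwhm_is_identity(self, rng):
        vol = rng.standard_normal((6, 6, 6))
        assert np.array_equal(smooth_gaussian(vol, 0.0, 3.0), vol)

    def test_impulse_matches_separable_kernel_oracle(self):
        vol = np.zeros((15, 15, 15))
        vol[7, 7, 7] = 1.0
        out = smooth_gaussian(vol, fwhm_mm=6.0, voxel_size_mm=3.0)
        sigma = 6.0 / (2 * np.sqrt(2 * np.log(2))) / 3.0
        assert np.isclose(sigma, 0.8493, atol=5e-4)
        r = int(6.0 * sigma + 0.5)
        i = np.arange(-r, r + 1)
        g = np.exp(-i ** 2 / (2 * sigma ** 2))
        g /= g.sum()
        oracle = np.einsum("i,j,k->ijk", g, g, g)
        window = out[7 - r:7 + r + 1, 7 - r:7 + r + 1, 7 - r:7 + r + 1]
        assert np.allclose(window, oracle, atol=1e-8)
        assert np.isclose(out.sum(), 1.0, rtol=1e-6)

    def test_constant_volume_unchanged_in_interior(self):
        vol = np.ones((16, 16, 16))
        out = smooth_gaussian(vol, 6.0, 3.0)
        assert np.allclose(out[6:-6, 6:-6, 6:-6], 1.0, atol=1e-9)

    def test_sum_preserved_for_interior_mass(self, rng):
        vol = np.zeros((20, 20, 20))
        vol[7:13, 7:13, 7:13] = rng.random((6, 6, 6))
        out = smooth_gaussian(vol, 6.0, 3.0)
        assert np.isclose(out.sum(), vol.sum(), rtol=1e-6)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            smooth_gaussian(np.zeros((4, 4, 4)), -1.0, 3.0)


class TestAlff:
    def test_constant_voxel_has_zero_alff(self):
        s = make_series(np.full((1, 1, 1, 80), 3.0))
        assert compute_alff(s).values[0, 0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_amplitude_linearity(self):
        a1 = compute_alff(sinusoid_series(0.05, amplitude=1.0)).values[0, 0, 0]
        a2 = compute_alff(sinusoid_series(0.05, amplitude=2.0)).values[0, 0, 0]
        assert a2 / a1 == pytest.approx(2.0, abs=1e-6)

    def test_white_noise_matches_periodogram_oracle(self, rng):
        x = rng.standard_normal(128)
        s = make_series(x.reshape(1, 1, 1, -1), tr_s=1.5)
        got = compute_alff(s, (0.01, 0.1)).values[0, 0, 0]
        freqs = np.fft.rfftfreq(128, 1.5)
        keep = (freqs >= 0.01) & (freqs <= 0.1)
        amp = np.abs(np.fft.rfft(x)) * 2.0 / 128
        assert got == pytest.approx(amp[keep].mean(), abs=1e-8)

    def test_unresolvable_band_rejected(self):
        s = make_series(np.zeros((1, 1, 1, 80)), tr_s=0.5)
        with pytest.raises(ValueError, match="band"):
            compute_alff(s, (0.001, 0.002))


class TestReho:
    def test_identical_neighbors_give_unit_concordance(self, rng):
        base = rng.standard_normal(30)
        vals = np.tile(base, (3, 3, 3, 1))
        s = make_series(vals)
        assert compute_reho(s).values[1, 1, 1] == pytest.approx(1.0, abs=1e-10)

    def test_reversed_pair_has_zero_concordance(self):
        x = np.arange(10.0)
        block = np.vstack([x, x[::-1]])
        assert kendall_w(block) == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_rank_oracle(self, rng):
        vals = rng.standard_normal((5, 5, 4, 25))
        s = make_series(vals)
        out = compute_reho(s, neighborhood=27)
        block = vals[0:3, 1:4, 1:4].reshape(27, 25)
        assert out.values[1, 2, 2] == pytest.approx(kendall_w(block), abs=1e-10)

    def test_monotone_time_transform_invariance(self, rng):
        vals = rng.standard_normal((4, 4, 3, 20))
        s1 = make_series(vals)
        s2 = make_series(np.exp(vals) + vals ** 3)  # strictly increasing map
        assert np.allclose(compute_reho(s1).values, compute_reho(s2).values,
                           atol=1e-12)

    def test_respects_mask_boundary(self, rng):
        vals = rng.standard_normal((4, 4, 3, 20))
        mask = np.ones((4, 4, 3), dtype=bool)
        mask[0] = False
        s = make_series(vals, mask=mask)
        out = compute_reho(s)
        sub = [vals[i, j, k] for i in (1, 2) for j in (0, 1) for k in (0, 1)]
        assert out.values[1, 0, 0] == pytest.approx(kendall_w(np.array(sub)),
                                                    abs=1e-10)
        assert out.values[0, 0, 0] == 0.0

    def test_bad_neighborhood_rejected(self, rng):
        with pytest.raises(ValueError):
            compute_reho(make_series(rng.standard_normal((3, 3, 3, 20))), 9)


class TestDegreeCentrality:
    def test_matches_full_correlation_matrix_oracle(self, rng):
        vals = rng.standard_normal((6, 6, 5, 40))
        vals[3, 3, 2] = vals[1, 1, 1]  # planted duplicate pair
        s = make_series(vals)
        out = compute_dc(s, r_threshold=0.25)
        flat = vals.reshape(-1, 40)
        corr = np.corrcoef(flat)
        np.fill_diagonal(corr, 0.0)
        expected = (corr > 0.25).sum(axis=1).reshape(6, 6, 5)
        assert np.array_equal(out.values, expected)
        assert out.values[1, 1, 1] >= 1 and out.values[3, 3, 2] >= 1

    def test_unit_threshold_counts_only_exact_duplicates(self, rng):
        vals = rng.standard_normal((4, 4, 2, 30))
        out = compute_dc(make_series(vals), r_threshold=1.0)
        assert np.all(out.values == 0)

    def test_shared_time_course_gives_complete_graph(self, rng):
        base = rng.standard_normal(30)
        scale = rng.uniform(0.5, 2.0, size=(3, 3, 2))
        vals = scale[..., None] * base
        out = compute_dc(make_series(vals), r_threshold=0.25)
        assert np.all(out.values == 3 * 3 * 2 - 1)

    def test_zero_variance_voxel_excluded(self, rng):
        vals = rng.standard_normal((3, 3, 2, 30))
        vals[0, 0, 0] = 5.0
        out = compute_dc(make_series(vals), r_threshold=0.25)
        assert out.values[0, 0, 0] == 0


class TestZscore:
    def test_mean_zero_sd_one_within_mask(self, rng):
        mask = rng.random((6, 6, 4)) > 0.3
        fmap = FeatureMap("ALFF", rng.standard_normal((6, 6, 4)) * 4 + 2, mask)
        z = zscore_map(fmap)
        inside = z.values[mask]
        assert abs(inside.mean()) < 1e-10 and abs(inside.std() - 1) < 1e-10
        assert np.isnan(z.values[~mask]).all()

    def test_affine_invariance_and_idempotence(self, rng):
        mask = np.ones((5, 5, 3), dtype=bool)
        vals = rng.standard_normal((5, 5, 3))
        z1 = zscore_map(FeatureMap("DC", vals, mask))
        z2 = zscore_map(FeatureMap("DC", 3.5 * vals - 11.0, mask))
        z3 = zscore_map(z1)
        assert np.allclose(z1.values, z2.values, atol=1e-10)
        assert np.allclose(z1.values, z3.values, atol=1e-10)

    def test_zero_sd_rejected(self):
        mask = np.ones((3, 3, 3), dtype=bool)
        with pytest.raises(DegeneracyError):
            zscore_map(FeatureMap("ALFF", np.ones((3, 3, 3)), mask))


def test_feature_zmaps_invariant_under_affine_intensity_rescale(rng):
    """ALFF/ReHo/DC z-maps are unchanged when voxel intensities are rescaled."""
    vals = rng.standard_normal((5, 5, 4, 64))
    s1 = make_series(vals)
    s2 = make_series(2.7 * vals)  # positive affine gain
    for compute in (compute_alff, compute_reho, compute_dc):
        m1 = zscore_map(compute(s1))
        m2 = zscore_map(compute(s2))
        assert np.allclose(m1.values, m2.values, atol=1e-6, equal_nan=True)
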