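"""Framewise displacement, nuisance regression, filtering, z-scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from capdyn.preproc import (
    build_nuisance_design,
    compute_fd,
    highpass,
    preprocess,
    regress_nuisance,
    scrub,
    smooth,
    zscore,
)
from capdyn.types import ConfigurationError, MotionParams

from conftest import make_series


def fd_oracle(values, radius):
    """Independent brute-force sum of absolute differentials."""
    n = values.shape[0]
    out = np.zeros(n)
    for t in range(1, n):
        s = 0.0
        for j in range(3):
            s += abs(values[t, j] - values[t - 1, j])
        for j in range(3, 6):
            s += abs(radius * (values[t, j] - values[t - 1, j]))
        out[t] = s
    return out


class TestFD:
    def test_zero_motion_gives_zero_fd(self):
        fd = compute_fd(MotionParams(np.zeros((10, 6))))
        np.testing.assert_array_equal(fd, 0.0)

    def test_translation_jump_arithmetic(self):
        vals = np.zeros((10, 6))
        vals[5:, :3] = 0.2  # +0.2 mm step on each axis at t=5
        fd = compute_fd(MotionParams(vals))
        assert fd[5] == pytest.approx(0.6)
        assert np.all(fd[np.arange(10) != 5] == 0.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        vals = np.random.default_rng(seed).normal(size=(20, 6))
        fd = compute_fd(MotionParams(vals), head_radius=50.0)
        np.testing.assert_allclose(fd, fd_oracle(vals, 50.0), atol=1e-12)

    def test_wrong_column_count_rejected(self):
        with pytest.raises(ConfigurationError):
            MotionParams(np.zeros((10, 5)))


class TestScrub:
    def test_no_motion_no_exclusion(self, small_series):
        out, n = scrub(small_series, np.zeros(small_series.n_frames), 0.5)
        assert n == 0 and out.frame_valid.all()

    def test_threshold_is_strict(self, small_series):
        fd = np.zeros(small_series.n_frames)
        fd[1], fd[2], fd[3] = 0.6, 0.4, 0.51
        out, n = scrub(small_series, fd, 0.5)
        assert n == 2
        assert not out.frame_valid[1] and not out.frame_valid[3]
        assert out.frame_valid[2]

    def test_frames_flagged_not_deleted(self, small_series):
        fd = np.ones(small_series.n_frames)
        out, _ = scrub(small_series, fd, 0.5)
        assert out.n_frames == small_series.n_frames

    def test_nonpositive_threshold_rejected(self, small_series):
        with pytest.raises(ConfigurationError):
            scrub(small_series, np.zeros(small_series.n_frames), 0.0)


class TestRegressNuisance:
    def test_constant_design_mean_centers(self, small_series):
        design = build_nuisance_design(small_series.n_frames, poly_order=0)
        out = regress_nuisance(small_series, design)
        np.testing.assert_allclose(out.data.mean(axis=0), 0.0, atol=1e-10)

    def test_design_column_space_annihilated(self, rng):
        series = make_series(rng=rng)
        wm = rng.normal(size=series.n_frames)
        design = build_nuisance_design(series.n_frames, wm=wm)
        # voxel 0 is an exact linear combination of design columns
        series.data[:, 0] = 2.0 + 3.0 * wm
        out = regress_nuisance(series, design)
        np.testing.assert_allclose(out.data[:, 0], 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_design(self, rng):
        series = make_series(rng=rng)
        design = build_nuisance_design(
            series.n_frames, wm=rng.normal(size=series.n_frames)
        )
        out = regress_nuisance(series, design)
        dots = design.matrix.T @ out.data
        assert np.abs(dots).max() < 1e-8

    def test_invalid_frames_untouched(self, rng):
        series = make_series(rng=rng)
        series.frame_valid[5] = False
        before = series.data[5].copy()
        out = regress_nuisance(series, build_nuisance_design(series.n_frames))
        np.testing.assert_array_equal(out.data[5], before)
        assert not out.frame_valid[5]

    def test_collinear_columns_pruned_with_warning(self, rng):
        wm = rng.normal(size=40)
        with pytest.warns(UserWarning, match="csf"):
            design = build_nuisance_design(40, wm=wm, csf=2 * wm)
        assert "csf" not in design.labels


class TestHighpass:
    def make_tone(self, freq, tr=1.3, n=300):
        t = np.arange(n) * tr
        data = np.tile(np.sin(2 * np.pi * freq * t)[:, None], (1, 4))
        return make_series(n_frames=n, grid_shape=(2, 2, 1), tr=tr, data=data)

    def test_slow_drift_removed(self):
        # residual RMS amplitude of a 0.002 Hz tone under 5% of input
        tone = self.make_tone(0.002)
        out = highpass(tone, cutoff=0.01)
        assert out.data.std() < 0.05 * tone.data.std()

    def test_passband_preserved(self):
        tone = self.make_tone(0.1)
        out = highpass(tone, cutoff=0.01)
        assert out.data.std() >= 0.95 * tone.data.std()

    def test_constant_series_zeroed(self):
        series = make_series(n_frames=50, grid_shape=(2, 2, 1), data=np.full((50, 4), 3.7))
        out = highpass(series, cutoff=0.01)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-10)

    def test_cutoff_at_nyquist_rejected(self, small_series):
        with pytest.raises(ConfigurationError):
            highpass(small_series, cutoff=0.5 / small_series.tr)


class TestZscore:
    def test_valid_frames_standardized(self, small_series):
        small_series.frame_valid[3] = False
        out = zscore(small_series)
        v = out.frame_valid
        np.testing.assert_allclose(out.data[v].mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.data[v].std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_constant_voxel_zeroed_and_flagged(self, small_series):
        small_series.data[:, 2] = 5.0
        out = zscore(small_series)
        np.testing.assert_array_equal(out.data[:, 2], 0.0)
        assert out.zero_variance[2] and not out.zero_variance[0]

    def test_two_frame_closed_form(self):
        # ddof=1 convention: (a, b) -> (-1/sqrt(2), +1/sqrt(2))
        series = make_series(n_frames=2, grid_shape=(1, 1, 1), data=np.array([[1.0], [3.0]]))
        out = zscore(series)
        np.testing.assert_allclose(
            out.data[:, 0], [-1 / np.sqrt(2), 1 / np.sqrt(2)], atol=1e-12
        )


def test_smoothing_reduces_spatial_roughness(rng):
    series = make_series(n_frames=3, grid_shape=(8, 8, 6), rng=rng)
    out = smooth(series, fwhm_vox=2.0)
    assert out.data.shape == series.data.shape
    # neighbouring-voxel differences shrink under Gaussian smoothing
    def roughness(s):
        vol = s.to_grid(0)
        return np.abs(np.diff(vol, axis=0)).mean()

    assert roughness(out) < roughness(series)


class TestPreprocessChain:
    def test_shapes_and_flags_preserved(self, tiny_cohort):
        _, bundles = tiny_cohort
        b = bundles[0]
        out, n_excl = preprocess(b.series, b.motion)
        assert out.data.shape == b.series.data.shape
        assert n_excl == int((~out.frame_valid).sum())
        assert np.all(np.isfinite(out.data))

    def test_rerun_is_bit_identical(self, tiny_cohort):
        _, bundles = tiny_cohort
        b = bundles[1]
        a, _ = preprocess(b.series, b.motion)
        c, _ = preprocess(b.series, b.motion)
        np.testing.assert_array_equal(a.data, c.data)
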