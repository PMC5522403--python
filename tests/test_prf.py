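"""CSS pRF model: forward predictions, fitting, averaging, coverage."""

import numpy as np
import pytest

from topomem import stimulus
from topomem.prf import (PRFFit, PRFParams, SearchConfig, VoxelTimeSeries,
                         average_runs_by_width, coverage_map, css_response,
                         double_gamma_hrf, fit_prf, gaussian_field,
                         predict_bold)
from topomem.stimulus import ApertureMovie, blank_movie, make_grid


def frame_movie(grid, masks, tr_s=2.0):
    return ApertureMovie(grid, np.asarray(masks, dtype=np.uint8), tr_s)


class TestGaussianField:
    def test_unit_peak_at_center(self):
        g = make_grid(10.0, 101)  # odd grid: pixel exactly at origin
        field = gaussian_field(PRFParams(0.0, 0.0, 2.0), g)
        assert field.max() == pytest.approx(1.0)
        assert field[50, 50] == pytest.approx(1.0)

    def test_value_at_one_sigma(self):
        g = make_grid(10.0, 101)
        sigma = 1.6
        # place the center exactly one sigma left of a known pixel center
        j = 70
        field = gaussian_field(PRFParams(g.coords[j] - sigma, g.coords[50], sigma), g)
        assert field[50, j] == pytest.approx(np.exp(-0.5), abs=1e-9)

    def test_integral_matches_2pi_sigma_squared(self):
        g = make_grid(10.0, 200)
        sigma = 1.0
        field = gaussian_field(PRFParams(0.0, 0.0, sigma), g)
        integral = field.sum() * g.pixel_area
        assert integral == pytest.approx(2 * np.pi * sigma ** 2, rel=1e-3)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            PRFParams(0.0, 0.0, 0.0)


class TestCssResponse:
    def test_empty_frames_give_zero(self, grid):
        m = blank_movie(grid, 4, 2.0)
        r = css_response(PRFParams(0, 0, 2.0, 0.5, 1.0), m)
        np.testing.assert_array_equal(r, 0.0)

    def test_linear_model_is_additive_over_disjoint_stimuli(self, grid):
        n = grid.n_pix
        a = np.zeros((1, n, n)); a[0, :, : n // 2] = 1
        b = np.zeros((1, n, n)); b[0, :, n // 2:] = 1
        p = PRFParams(1.0, -2.0, 2.0, 1.0, 1.3)
        ra = css_response(p, frame_movie(grid, a))
        rb = css_response(p, frame_movie(grid, b))
        rab = css_response(p, frame_movie(grid, a + b))
        assert rab[0] == pytest.approx(ra[0] + rb[0], rel=1e-12)

    def test_compressive_model_is_subadditive(self, grid):
        n = grid.n_pix
        a = np.zeros((1, n, n)); a[0, :, : n // 2] = 1
        b = np.zeros((1, n, n)); b[0, :, n // 2:] = 1
        p = PRFParams(0.0, 0.0, 3.0, 0.5, 1.0)
        ra = css_response(p, frame_movie(grid, a))[0]
        rb = css_response(p, frame_movie(grid, b))[0]
        rab = css_response(p, frame_movie(grid, a + b))[0]
        assert rab < ra + rb

    def test_monotone_in_stimulus_area_and_linear_in_beta(self, grid):
        rng = np.random.default_rng(0)
        n = grid.n_pix
        base = (rng.uniform(size=(3, n, n)) < 0.2).astype(np.uint8)
        grown = base.copy()
        grown[:, : n // 4, :] = 1
        p = PRFParams(2.0, 1.0, 2.0, 0.6, 1.0)
        r_base = css_response(p, frame_movie(grid, base))
        r_grown = css_response(p, frame_movie(grid, grown))
        assert (r_grown >= r_base - 1e-12).all()
        p2 = PRFParams(2.0, 1.0, 2.0, 0.6, 2.0)
        np.testing.assert_allclose(
            css_response(p2, frame_movie(grid, base)), 2 * r_base, rtol=0,
            atol=1e-14)


class TestPredictBold:
    def test_unit_impulse_hrf_is_identity(self, small_movie):
        p = PRFParams(3.0, 1.0, 1.5, 0.7, 1.0)
        pred = predict_bold(p, small_movie, np.array([1.0]))
        np.testing.assert_allclose(pred.values, css_response(p, small_movie))

    def test_zero_movie_predicts_zero(self, grid):
        m = blank_movie(grid, 10, 2.0)
        pred = predict_bold(PRFParams(0, 0, 1.0), m, double_gamma_hrf(2.0))
        np.testing.assert_array_equal(pred.values, 0.0)

    def test_single_frame_stimulus_yields_shifted_hrf(self, grid):
        n = grid.n_pix
        frames = np.zeros((20, n, n), dtype=np.uint8)
        frames[4] = 1  # full field at frame 4
        m = frame_movie(grid, frames)
        p = PRFParams(0.0, 0.0, 2.0, 0.6, 1.7)
        hrf = double_gamma_hrf(2.0)
        amp = css_response(p, m)[4]
        pred = predict_bold(p, m, hrf).values
        expected = np.zeros(20)
        expected[4:] = amp * hrf[:16]
        np.testing.assert_allclose(pred, expected, atol=1e-12)

    def test_empty_hrf_rejected(self, small_movie):
        with pytest.raises(ValueError):
            predict_bold(PRFParams(0, 0, 1.0), small_movie, np.array([]))


class TestFitPrf:
    def test_noiseless_recovery_of_known_parameters(self, mapping_movie):
        truth = PRFParams(5.0, -3.0, 1.5, 0.6, 2.0)
        hrf = double_gamma_hrf(mapping_movie.tr_s)
        ts = predict_bold(truth, mapping_movie, hrf)
        fit = fit_prf(ts, mapping_movie)
        assert abs(fit.params.x0 - truth.x0) < 0.1
        assert abs(fit.params.y0 - truth.y0) < 0.1
        assert abs(fit.params.sigma - truth.sigma) / truth.sigma < 0.05
        assert abs(fit.params.n_exp - truth.n_exp) < 0.05
        assert fit.variance_explained > 0.999
        assert fit.eccentricity == pytest.approx(np.hypot(5, -3), abs=0.15)

    def test_pure_noise_voxel_has_low_variance_explained(self, small_movie):
        rng = np.random.default_rng(1)
        ts = VoxelTimeSeries(rng.normal(size=small_movie.n_frames))
        fit = fit_prf(ts, small_movie)
        assert fit.variance_explained < 0.3

    def test_css_fit_not_worse_than_linear_on_linear_voxel(self, small_movie):
        truth = PRFParams(-4.0, 2.0, 2.0, 1.0, 1.0)
        hrf = double_gamma_hrf(small_movie.tr_s)
        ts = predict_bold(truth, small_movie, hrf)
        css = fit_prf(ts, small_movie)
        linear_cfg = SearchConfig(n_exps=(1.0,), n_bounds=(1.0, 1.0))
        lin = fit_prf(ts, small_movie, linear_cfg)
        assert css.variance_explained >= lin.variance_explained - 1e-9

    def test_constant_series_flagged_not_converged(self, small_movie):
        ts = VoxelTimeSeries(np.full(small_movie.n_frames, 3.0))
        fit = fit_prf(ts, small_movie)
        assert not fit.converged
        assert fit.variance_explained == 0.0

    def test_nan_series_rejected(self, small_movie):
        vals = np.zeros(small_movie.n_frames)
        vals[3] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            fit_prf(VoxelTimeSeries(vals), small_movie)

    def test_length_mismatch_rejected(self, small_movie):
        with pytest.raises(ValueError, match="length"):
            fit_prf(VoxelTimeSeries(np.zeros(5)), small_movie)


class TestAverageRunsByWidth:
    def test_identical_runs_average_to_themselves(self):
        r = VoxelTimeSeries(np.arange(5.0), width_deg=1.0)
        out = average_runs_by_width([r, r])
        np.testing.assert_array_equal(out[1.0].values, r.values)

    def test_pointwise_mean(self):
        r1 = VoxelTimeSeries(np.ones(4), width_deg=2.0)
        r2 = VoxelTimeSeries(np.full(4, 3.0), width_deg=2.0)
        out = average_runs_by_width([r1, r2])
        np.testing.assert_array_equal(out[2.0].values, 2.0)

    def test_three_widths_stay_separate(self):
        runs = [VoxelTimeSeries(np.full(4, w), width_deg=w)
                for w in (1.0, 2.0, 3.0) for _ in range(2)]
        out = average_runs_by_width(runs)
        assert sorted(out) == [1.0, 2.0, 3.0]

    def test_length_mismatch_within_width_rejected(self):
        runs = [VoxelTimeSeries(np.zeros(4), width_deg=1.0),
                VoxelTimeSeries(np.zeros(5), width_deg=1.0)]
        with pytest.raises(ValueError, match="mismatch"):
            average_runs_by_width(runs)


class TestCoverage:
    def fit(self, x0, y0, sigma, ve=0.8):
        return PRFFit(PRFParams(x0, y0, sigma), variance_explained=ve)

    def test_single_voxel_peaks_at_its_center(self, grid):
        # center on an exact pixel so the unit peak is sampled
        x0 = float(grid.coords[35])
        y0 = float(grid.coords[24])
        cov = coverage_map([self.fit(x0, y0, 2.0)], grid)
        xx, yy = grid.meshgrid()
        peak = np.unravel_index(np.argmax(cov.density), cov.density.shape)
        assert xx[peak] == pytest.approx(x0, abs=grid.pixel_spacing)
        assert yy[peak] == pytest.approx(y0, abs=grid.pixel_spacing)
        assert cov.density.max() == pytest.approx(1.0, abs=1e-9)

    def test_left_hemifield_voxels_leave_right_field_empty(self, grid):
        fits = [self.fit(-6.0, y, 0.8) for y in (-3.0, 0.0, 3.0)]
        cov = coverage_map(fits, grid)
        left, right = cov.hemifield_integrals()
        assert right < 0.05 * left

    def test_contralateral_bias_produces_density_asymmetry(self, grid):
        rng = np.random.default_rng(2)
        fits = []
        for _ in range(30):
            side = 1.0 if rng.uniform() < 0.9 else -1.0  # 90% right (contra) field
            fits.append(self.fit(side * rng.uniform(2, 8),
                                 rng.uniform(-6, 6), rng.uniform(1, 3)))
        cov = coverage_map(fits, grid)
        left, right = cov.hemifield_integrals()
        assert right > left

    def test_threshold_excludes_bad_fits_and_warns_when_empty(self, grid):
        bad = [self.fit(0, 0, 2.0, ve=0.01)]
        with pytest.warns(UserWarning, match="empty"):
            cov = coverage_map(bad, grid, ve_threshold=0.1)
        assert cov.density.sum() == 0.0
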