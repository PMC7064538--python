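import numpy as np
import pytest

from iplscan import rois as R
from iplscan.errors import EmptyTraceError, UndefinedQualityError
from iplscan.synth import Movie


def make_movie(pixels, artefact_lines=0, pixel_size=1.0):
    return Movie(
        pixels=np.asarray(pixels, dtype=float),
        pixel_size_um=pixel_size,
        line_period_ms=1.6,
        artefact_lines=artefact_lines,
        frame_rate_hz=10.0,
    )


class TestCorrelationImage:
    def test_identical_traces_give_unit_interior_correlation(self, rng):
        base = rng.standard_normal(300)
        movie = make_movie(np.broadcast_to(base, (6, 5, 300)).copy())
        ci = R.correlation_image(movie)
        assert np.allclose(ci.rho_local[ci.valid_mask], 1.0)

    def test_independent_noise_centred_on_zero(self, rng):
        movie = make_movie(rng.standard_normal((20, 20, 400)))
        ci = R.correlation_image(movie)
        assert abs(ci.rho_local[ci.valid_mask].mean()) < 0.01

    def test_three_by_three_matches_brute_force_pairwise_oracle(self, rng):
        px = rng.standard_normal((3, 3, 50))
        movie = make_movie(px)
        ci = R.correlation_image(movie)
        # brute force: centre pixel vs its 8 neighbours
        centre = px[1, 1]
        rs = []
        for dx in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dz) == (0, 0):
                    continue
                rs.append(np.corrcoef(centre, px[1 + dx, 1 + dz])[0, 1])
        assert ci.rho_local[1, 1] == pytest.approx(np.mean(rs), abs=1e-12)

    def test_constant_pixels_invalid_and_zero(self, rng):
        px = rng.standard_normal((4, 4, 60))
        px[2, 2] = 5.0  # constant trace
        ci = R.correlation_image(make_movie(px))
        assert not ci.valid_mask[2, 2]
        assert ci.rho_local[2, 2] == 0.0

    def test_all_constant_movie_warns_not_raises(self):
        with pytest.warns(UserWarning):
            ci = R.correlation_image(make_movie(np.ones((4, 4, 10))))
        assert not ci.valid_mask.any()

    def test_artefact_lines_excluded(self, rng):
        px = rng.standard_normal((5, 6, 80))
        ci = R.correlation_image(make_movie(px, artefact_lines=2))
        assert not ci.valid_mask[:, :2].any()

    def test_invariant_to_affine_intensity_rescaling(self, rng):
        px = rng.standard_normal((6, 6, 120))
        ci1 = R.correlation_image(make_movie(px))
        ci2 = R.correlation_image(make_movie(3.7 * px + 11.0))
        np.testing.assert_allclose(ci1.rho_local, ci2.rho_local, atol=1e-10)


class TestLineThresholds:
    def test_constant_line_threshold_equals_value(self):
        rho = np.full((8, 3), 0.4)
        ci = R.CorrelationImage(rho_local=rho, valid_mask=np.ones_like(rho, dtype=bool))
        np.testing.assert_allclose(R.line_thresholds(ci), [0.4, 0.4, 0.4])

    def test_linear_interpolation_convention(self):
        # values 1..10: the 70th percentile under linear interpolation is 7.3
        rho = np.arange(1.0, 11.0).reshape(10, 1)
        ci = R.CorrelationImage(rho_local=rho, valid_mask=np.ones_like(rho, dtype=bool))
        assert R.line_thresholds(ci)[0] == pytest.approx(7.3)

    def test_empty_line_gets_infinite_threshold(self):
        rho = np.zeros((4, 2))
        valid = np.zeros((4, 2), dtype=bool)
        valid[:, 1] = True
        ci = R.CorrelationImage(rho_local=rho, valid_mask=valid)
        with pytest.warns(UserWarning):
            thr = R.line_thresholds(ci)
        assert np.isinf(thr[0]) and np.isfinite(thr[1])


class TestGrowAndFilter:
    def test_nothing_above_threshold_gives_empty_list(self, rng):
        movie = make_movie(rng.standard_normal((6, 6, 30)))
        ci = R.correlation_image(movie)
        thr = np.full(6, np.inf)
        assert R.grow_rois(ci, thr, movie) == []

    def test_single_blob_becomes_single_roi(self, rng):
        rho = np.zeros((8, 8))
        valid = np.ones((8, 8), dtype=bool)
        rho[2:4, 3:5] = [[0.8, 0.7], [0.6, 0.9]]
        ci = R.CorrelationImage(rho_local=rho, valid_mask=valid)
        movie = make_movie(rng.standard_normal((8, 8, 20)))
        out = R.grow_rois(ci, np.full(8, 0.5), movie)
        assert len(out) == 1
        assert out[0].area_px == 4
        assert out[0].seed == (3, 4)  # highest-correlation pixel
        assert out[0].mask[out[0].seed]

    def test_diagonal_pixels_are_separate_rois(self, rng):
        rho = np.zeros((6, 6))
        rho[1, 1] = rho[2, 2] = 0.9  # touching only diagonally: 4-connectivity splits
        ci = R.CorrelationImage(rho_local=rho, valid_mask=np.ones((6, 6), dtype=bool))
        movie = make_movie(rng.standard_normal((6, 6, 20)))
        assert len(R.grow_rois(ci, np.full(6, 0.5), movie)) == 2

    @pytest.mark.parametrize(
        "area,kept",
        [(3, True), (12, True), (40, False), (1, True)],
    )
    def test_effective_diameter_bounds(self, area, kept, rng):
        # d = 2 sqrt(area/pi) at 1 um/px: 3 px -> 1.95 um kept; 40 px -> 7.14 um removed
        rec = R.ROIRecord(
            roi_id=0, batch_id="b", mask=np.ones((1, 1), dtype=bool), seed=(0, 0),
            seed_corr=1.0, area_px=area, effective_diameter_um=R.effective_diameter_um(area, 1.0),
        )
        out = R.filter_diameter([rec], 1.0)
        assert (len(out) == 1) is kept

    def test_diameter_formula(self):
        assert R.effective_diameter_um(3, 1.0) == pytest.approx(1.9544, abs=1e-3)
        assert R.effective_diameter_um(40, 1.0) == pytest.approx(7.1365, abs=1e-3)


class TestQualityIndex:
    def test_identical_repeats_score_one(self, rng):
        r = np.tile(rng.standard_normal(500), (4, 1))
        assert R.quality_index(r) == 1.0

    def test_pure_noise_scores_about_one_over_r(self, rng):
        # Monte-Carlo oracle: E[var(mean)/mean(var)] = 1/R for i.i.d. noise
        vals = [R.quality_index(rng.standard_normal((4, 4096))) for _ in range(30)]
        assert np.mean(vals) == pytest.approx(0.25, abs=0.01)

    def test_single_repeat_rejected(self, rng):
        with pytest.raises(UndefinedQualityError):
            R.quality_index(rng.standard_normal((1, 100)))


class TestExtractTraces:
    def test_single_pixel_mask_returns_pixel_series(self, rng):
        px = rng.standard_normal((5, 5, 40))
        movie = make_movie(px)
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 3] = True
        rec = R.ROIRecord(roi_id=0, batch_id="b", mask=mask, seed=(2, 3),
                          seed_corr=1.0, area_px=1, effective_diameter_um=1.1)
        out = R.extract_traces(movie, [rec])
        np.testing.assert_array_equal(out[0], px[2, 3])

    def test_two_pixel_mask_averages(self, rng):
        px = rng.standard_normal((5, 5, 40))
        movie = make_movie(px)
        mask = np.zeros((5, 5), dtype=bool)
        mask[1, 1] = mask[1, 2] = True
        rec = R.ROIRecord(roi_id=0, batch_id="b", mask=mask, seed=(1, 1),
                          seed_corr=1.0, area_px=2, effective_diameter_um=1.6)
        out = R.extract_traces(movie, [rec])
        np.testing.assert_allclose(out[0], (px[1, 1] + px[1, 2]) / 2)

    def test_mask_inside_artefact_lines_rejected(self, rng):
        movie = make_movie(rng.standard_normal((5, 5, 40)), artefact_lines=3)
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 1] = True  # z=1 < artefact_lines
        rec = R.ROIRecord(roi_id=0, batch_id="b", mask=mask, seed=(2, 1),
                          seed_corr=1.0, area_px=1, effective_diameter_um=1.1)
        with pytest.raises(EmptyTraceError):
            R.extract_traces(movie, [rec])
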