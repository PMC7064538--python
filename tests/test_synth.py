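import numpy as np
import pytest

from iplscan import synth
from iplscan.encoding import build_kernel, predict_response
from iplscan.errors import ConfigError, PlacementError


class TestPopulation:
    def test_seed_determinism(self):
        a, ta = synth.sample_population(25, 3, seed=7)
        b, tb = synth.sample_population(25, 3, seed=7)
        assert synth.population_table(a).equals(synth.population_table(b))
        np.testing.assert_array_equal(ta.psi, tb.psi)

    def test_depths_span_ipl_and_polarity_follows_centre(self):
        rois, truth = synth.sample_population(200, 4, seed=1)
        tab = synth.population_table(rois)
        assert tab.depth.between(-1, 2).all()
        on = tab.polarity == "On"
        assert (tab.depth[on] < truth.centre).all()
        assert (tab.depth[~on] >= truth.centre).all()
        assert (tab.amplitude[on] > 0).all() and (tab.amplitude[~on] < 0).all()

    def test_zero_batch_spread_gives_pure_depth_profile(self):
        cfg = synth.PopulationConfig(psi_sd=0.0)
        rois, truth = synth.sample_population(50, 5, cfg, seed=2)
        np.testing.assert_array_equal(truth.psi, np.zeros(5))
        tab = synth.population_table(rois)
        # stretch depends on the depth bin only
        bins = np.digitize(tab.depth, truth.bin_edges[1:-1])
        for b in np.unique(bins):
            assert tab.stretch[bins == b].nunique() == 1

    def test_centre_rois_faster_than_border_rois(self):
        rois, truth = synth.sample_population(400, 2, seed=3)
        tab = synth.population_table(rois)
        centre = tab.stretch[(tab.depth - 0.5).abs() < 0.4]
        border = tab.stretch[(tab.depth - 0.5).abs() > 1.0]
        assert centre.mean() > border.mean()

    def test_more_batches_than_rois_rejected(self):
        with pytest.raises(ConfigError):
            synth.sample_population(3, 5)


class TestTraces:
    def test_noiseless_repeats_equal_model_prediction(self, stim):
        cfg = synth.PopulationConfig(noise_sigma=0.0)
        rois, truth = synth.sample_population(6, 2, cfg, seed=4)
        tr = synth.simulate_traces(rois, truth, stim, repeats=3, seed=5)
        # every repeat identical and equal to the single prediction code path
        for r in range(3):
            np.testing.assert_array_equal(tr.repeats[:, r, :], tr.clean)
        x = stim.samples
        xz = (x - x.mean()) / x.std()
        roi = rois[0]
        expect = predict_response(
            build_kernel(truth.kernel_coef, roi.stretch), roi.amplitude, roi.offset, xz
        )
        np.testing.assert_allclose(tr.clean[0], expect, rtol=0, atol=1e-12)

    def test_batch_shift_acts_as_pure_temporal_rescaling(self, stim):
        """Two ROIs identical except for a psi-shifted stretch differ only by
        kernel rescaling, i.e. each equals the direct prediction at its alpha."""
        cfg = synth.PopulationConfig(noise_sigma=0.0)
        rois, truth = synth.sample_population(2, 1, cfg, seed=6)
        x = stim.samples
        xz = (x - x.mean()) / x.std()
        base = rois[0]
        for dpsi in (0.1, -0.2):
            stretched = synth.GroundTruthROI(
                roi_id=99, batch_id=base.batch_id, depth=base.depth,
                polarity=base.polarity, amplitude=base.amplitude,
                offset=base.offset, stretch=base.stretch + dpsi, noise_sigma=0.0,
            )
            tr = synth.simulate_traces([stretched], truth, stim, repeats=1, seed=0)
            oracle = predict_response(
                build_kernel(truth.kernel_coef, base.stretch + dpsi),
                base.amplitude, base.offset, xz,
            )
            np.testing.assert_allclose(tr.clean[0], oracle, atol=1e-12)

    def test_zero_repeats_rejected(self, stim):
        rois, truth = synth.sample_population(3, 1, seed=1)
        with pytest.raises(ConfigError):
            synth.simulate_traces(rois, truth, stim, repeats=0)


class TestMovie:
    def test_geometry_and_artefact_lines(self, rendered_movie):
        mv = rendered_movie["movie"]
        assert mv.pixels.shape[:2] == (64, 56)
        assert mv.artefact_lines < mv.pixels.shape[1]
        # artefact lines carry much higher variance than background
        art_var = mv.pixels[:, : mv.artefact_lines, :].var()
        cfg = synth.MovieConfig()
        assert art_var > 10 * cfg.pixel_noise_sigma**2

    def test_masks_are_disjoint_and_in_range_sizes(self, rendered_movie):
        masks = rendered_movie["mtruth"].masks
        assert masks.sum(axis=0).max() <= 1
        areas = masks.sum(axis=(1, 2))
        cfg = synth.MovieConfig()
        assert areas.min() >= cfg.area_range_px[0]
        assert areas.max() <= cfg.area_range_px[1]

    def test_zero_pixel_noise_gives_perfect_within_roi_correlation(self, stim):
        cfg = synth.PopulationConfig(noise_sigma=0.2)
        rois, truth = synth.sample_population(5, 1, cfg, seed=8)
        tr = synth.simulate_traces(rois, truth, stim, repeats=2, seed=9)
        mcfg = synth.MovieConfig(pixel_noise_sigma=0.0, neuropil_coverage=0.0)
        mv, mtruth = synth.render_movie(tr, rois, mcfg, seed=10)
        for i in range(5):
            pix = mv.pixels[mtruth.masks[i]]
            cc = np.corrcoef(pix)
            assert cc.min() > 0.999999

    def test_impossible_placement_raises(self, stim):
        rois, truth = synth.sample_population(200, 1, seed=11)
        tr = synth.simulate_traces(rois, truth, stim, repeats=1, seed=12)
        mcfg = synth.MovieConfig(nx=16, nz=20, max_retries=10)
        with pytest.raises(PlacementError):
            synth.render_movie(tr, rois, mcfg, seed=13)


def test_movie_tiff_round_trip(tmp_path, rendered_movie):
    import tifffile

    mv = rendered_movie["movie"]
    path = tmp_path / "movie.tif"
    synth.write_movie_tiff(mv, path)
    back = tifffile.imread(path)
    assert back.shape == (mv.pixels.shape[2], mv.pixels.shape[1], mv.pixels.shape[0])
    np.testing.assert_array_equal(back[0].T, mv.pixels[:, :, 0])
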