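"""Generator behaviour: scene fields, aggregate statistics, survey and
rendering geometry, all against analytic or ground-truth oracles."""

import numpy as np
import pytest
from scipy import stats

from underice.detection import crop_frame, label_regions, qc_frames, threshold_green
from underice.geometry import CameraCalib
from underice.synthetic import (
    Clustering,
    IceSceneParams,
    RenderParams,
    SizeLaw,
    SurveyParams,
    TrueAggregate,
    gen_aggregate_field,
    gen_ice_scene,
    render_frame,
    sample_truncated_powerlaw,
    simulate_survey,
    truncated_powerlaw_cdf,
)
from underice.spatial_stats import fit_size_distribution, lloyd_patchiness

FLAT = IceSceneParams(draft_std=0.0, n_ridges=0, mean_draft=1.0)


class TestIceScene:
    def test_constant_draft_has_zero_roughness(self):
        scene = gen_ice_scene((100.0, 100.0), FLAT, seed=0)
        assert np.allclose(scene.draft, 1.0)
        assert np.allclose(scene.roughness, 0.0)

    def test_fixed_seed_reproduces_fields(self):
        a = gen_ice_scene((50.0, 40.0), IceSceneParams(), seed=11)
        b = gen_ice_scene((50.0, 40.0), IceSceneParams(), seed=11)
        assert np.array_equal(a.draft, b.draft)
        assert np.array_equal(a.transmittance, b.transmittance)

    def test_ridge_amplitude_reached_along_keel(self):
        p = IceSceneParams(draft_std=0.0, mean_draft=0.0, n_ridges=1, ridge_amplitude=3.0)
        scene = gen_ice_scene((60.0, 60.0), p, seed=5)
        assert scene.draft.max() >= 3.0 * 0.99  # keel crest may fall between cells

    def test_field_invariants(self):
        scene = gen_ice_scene((40.0, 40.0), IceSceneParams(), seed=3)
        assert (scene.draft >= 0).all()
        assert (scene.roughness >= 0).all()
        assert ((scene.transmittance >= 0) & (scene.transmittance <= 1)).all()
        assert scene.draft.shape == scene.roughness.shape == scene.transmittance.shape

    @pytest.mark.parametrize("extent", [(0.0, 10.0), (10.0, -1.0)])
    def test_bad_extent_rejected(self, extent):
        with pytest.raises(ValueError):
            gen_ice_scene(extent, IceSceneParams(), seed=0)


class TestAggregateField:
    def test_poisson_limit_without_clustering(self):
        scene = gen_ice_scene((100.0, 100.0), FLAT, seed=0)
        lam = 0.5
        counts = [
            len(gen_aggregate_field(scene, intensity=lam, clustering=None, seed=s))
            for s in range(40)
        ]
        mean_expect = lam * 100 * 100
        # Poisson(5000) mean over 40 draws: tolerance 4 sigma
        tol = 4 * np.sqrt(mean_expect / 40)
        assert abs(np.mean(counts) - mean_expect) < tol
        # gridded counts of one realisation are Poisson-dispersed
        aggs = gen_aggregate_field(scene, intensity=lam, clustering=None, seed=1)
        edges = np.arange(0, 101, 5)
        h, _, _ = np.histogram2d(
            [a.x for a in aggs], [a.y for a in aggs], bins=(edges, edges)
        )
        assert 0.9 < lloyd_patchiness(h.ravel()).P < 1.1

    def test_size_slope_recovered_by_refit(self):
        scene = gen_ice_scene((50.0, 50.0), FLAT, seed=0)
        aggs = gen_aggregate_field(
            scene, n=5000, size_law=SizeLaw(b=-3.0, d_min=1.0, d_max=30.0),
            clustering=None, seed=2,
        )
        fit = fit_size_distribution([a.diameter for a in aggs], d_min=1.0)
        assert abs(fit.b - (-3.0)) < 0.3

    def test_diameters_pass_ks_against_target_law(self):
        scene = gen_ice_scene((50.0, 50.0), FLAT, seed=0)
        law = SizeLaw(b=-2.2, d_min=1.0, d_max=30.0)
        aggs = gen_aggregate_field(scene, n=5000, size_law=law, clustering=None, seed=3)
        d = np.array([a.diameter for a in aggs])
        res = stats.kstest(d, lambda x: truncated_powerlaw_cdf(x, law.b, law.d_min, law.d_max))
        assert res.pvalue > 0.01

    def test_draft_affinity_concentrates_on_thin_ice(self):
        scene = gen_ice_scene((80.0, 80.0), IceSceneParams(), seed=7)
        aggs = gen_aggregate_field(scene, n=2000, clustering=None, draft_affinity=3.0, seed=8)
        mean_at_aggs = np.mean([scene.draft_at(a.x, a.y) for a in aggs])
        assert mean_at_aggs < scene.draft.mean()

    def test_degenerate_size_law_rejected(self):
        with pytest.raises(ValueError):
            SizeLaw(b=-3.0, d_min=5.0, d_max=5.0)
        with pytest.raises(ValueError):
            SizeLaw(b=0.5, d_min=1.0, d_max=10.0)

    def test_fixed_seed_reproduces_field(self):
        scene = gen_ice_scene((30.0, 30.0), FLAT, seed=0)
        a = gen_aggregate_field(scene, intensity=1.0, seed=9)
        b = gen_aggregate_field(scene, intensity=1.0, seed=9)
        assert [(p.x, p.y, p.diameter) for p in a] == [(q.x, q.y, q.diameter) for q in b]


class TestSurvey:
    def test_frame_count_follows_track_arithmetic(self):
        # 500 m single-line track at 0.5 m/s with a frame every 5 s -> 200 frames
        scene = gen_ice_scene((504.0, 10.0), FLAT, seed=0)
        survey = SurveyParams(speed=0.5, frame_interval=5.0, line_spacing=100.0,
                              margin=2.0, depth_noise=0.0, tilt_noise=0.0,
                              position_noise_sd=0.0)
        frames, _ = simulate_survey(scene, [], survey, rendering=None)
        assert len(frames) == 200

    def test_noise_free_flat_ice_gives_constant_nav(self):
        scene = gen_ice_scene((50.0, 20.0), FLAT, seed=0)
        survey = SurveyParams(depth_noise=0.0, tilt_noise=0.0, position_noise_sd=0.0)
        frames, _ = simulate_survey(scene, [], survey, rendering=None)
        assert len({f.depth for f in frames}) == 1
        assert len({f.altimeter for f in frames}) == 1
        assert frames[0].depth == pytest.approx(2.0)  # 1 m draft + 1 m standoff

    def test_injected_tilt_removed_by_qc(self):
        scene = gen_ice_scene((50.0, 20.0), FLAT, seed=0)
        survey = SurveyParams(depth_noise=0.0, tilt_noise=0.0, position_noise_sd=0.0)
        frames, _ = simulate_survey(scene, [], survey, rendering=None)
        k = 7
        for f in frames[3 : 3 + k]:
            f.tilt = 15.0
        valid, report = qc_frames(frames)
        assert report.n_discarded_tilt == k
        assert len(valid) == len(frames) - k

    def test_truth_rows_match_rendered_instances(self):
        scene = gen_ice_scene((40.0, 40.0), FLAT, seed=0)
        aggs = gen_aggregate_field(scene, intensity=2.0, clustering=None, seed=4)
        frames, truth = simulate_survey(scene, aggs, SurveyParams(seed=1))
        assert (truth["n_pixels"] > 0).all()
        assert set(truth["frame_id"]).issubset({f.frame_id for f in frames})
        assert truth["agg_id"].isin([a.agg_id for a in aggs]).all()

    def test_fixed_seed_reproduces_frames(self):
        scene = gen_ice_scene((30.0, 20.0), FLAT, seed=0)
        aggs = gen_aggregate_field(scene, intensity=1.0, seed=2)
        f1, t1 = simulate_survey(scene, aggs, SurveyParams(seed=5))
        f2, t2 = simulate_survey(scene, aggs, SurveyParams(seed=5))
        assert all(np.array_equal(a.pixels, b.pixels) for a, b in zip(f1, f2))
        assert t1.equals(t2)


class TestRendering:
    def test_projected_area_matches_camera_model(self, render_single):
        # 4 cm aggregate at 1 m standoff: pi * (20 mm)^2 / (4.5 mm/px)^2 ~ 62 px
        frame = render_single(4.0, standoff=1.0)
        mask = threshold_green(crop_frame(frame))
        regions = label_regions(mask)
        assert len(regions) == 1
        assert regions[0].pixel_area == pytest.approx(62.0, abs=8)

    def test_empty_scene_gives_empty_mask(self, calib):
        from underice.detection import Frame

        geom = Frame(0, 0.0, 2.0, 0.0, 1.0, 0.0, 0.0)
        frame = render_frame(geom, None, [], calib, RenderParams())
        assert not threshold_green(crop_frame(frame)).any()

    def test_strong_gradient_creates_flagged_false_positives(self, calib):
        # push the dark corner of the background below the threshold band
        from underice.detection import Frame

        geom = Frame(0, 0.0, 2.0, 0.0, 1.0, 0.0, 0.0)
        rendering = RenderParams(background_green_mean=130.0, gradient_amp=60.0,
                                 noise_sd=0.0)
        frame = render_frame(geom, None, [], calib, rendering)
        mask = threshold_green(crop_frame(frame))
        assert mask.any()  # detections with no ground truth: false positives

    def test_degenerate_dynamic_range_rejected(self):
        with pytest.raises(ValueError):
            RenderParams(background_green_mean=80.0, aggregate_green=90.0)
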