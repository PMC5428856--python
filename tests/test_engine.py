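"""Per-frame analysis engine: background, finding, filtering, fitting."""

import numpy as np
import pytest

from splinepsf.config import AnalysisConfig
from splinepsf.engine import (FrameState, analyze_frame, estimate_background,
                              find_peaks, proximity_filter)
from splinepsf.fit import crlb
from splinepsf.simulate import render_movie, uniform_emitters


class _Loc:
    """Minimal localization stand-in for the proximity filter."""

    def __init__(self, x, y, photons, status="converged"):
        self.x, self.y, self.photons, self.status = x, y, photons, status


class TestBackground:
    def test_constant_image_returns_that_constant(self):
        bg = estimate_background(np.full((32, 32), 7.0))
        assert np.allclose(bg, 7.0, atol=1e-9)

    def test_single_emitter_barely_perturbs_far_background(self, spline_astig):
        truth = uniform_emitters(1, shape=(64, 64), n_frames=1, seed=0,
                                 margin=28, photons=4000, background=100)
        frame = render_movie(truth, spline_astig, noise=False)[0]
        bg = estimate_background(frame)
        far = np.ones_like(frame, dtype=bool)
        y, x = int(truth.y[0]), int(truth.x[0])
        far[max(y - 24, 0):y + 24, max(x - 24, 0):x + 24] = False
        assert np.all(np.abs(bg[far] - 100.0) < 5.0)

    def test_pure_background_movie_estimated_within_two_photons(self):
        rng = np.random.default_rng(1)
        frame = rng.poisson(100.0, size=(128, 128)).astype(float)
        bg = estimate_background(frame)
        assert abs(bg.mean() - 100.0) < 2.0


class TestFindPeaks:
    def test_blank_residual_yields_no_candidates(self, spline_astig):
        assert find_peaks(np.zeros((64, 64)), spline_astig, [0.0], 6.0,
                          100.0) == []

    def test_single_noise_free_emitter_found_at_its_pixel(self, spline_astig):
        truth = uniform_emitters(1, shape=(64, 64), n_frames=1, seed=3,
                                 margin=20, photons=4000, background=0)
        frame = render_movie(truth, spline_astig, noise=False)[0]
        cands = find_peaks(frame, spline_astig, [0.0], 6.0, 100.0)
        assert len(cands) == 1
        # defocus elongation can move the matched-filter maximum by a pixel
        assert abs(cands[0].x - truth.x[0]) <= 1.0
        assert abs(cands[0].y - truth.y[0]) <= 1.0

    def test_two_emitters_ten_pixels_apart_both_found(self, spline_astig):
        from splinepsf.simulate import GroundTruth

        truth = GroundTruth(frame=np.zeros(2, int),
                            x=np.array([25.0, 35.0]), y=np.array([30.0, 30.0]),
                            z=np.zeros(2), photons=np.full(2, 4000.0),
                            background=100.0, shape=(64, 64), n_frames=1)
        frame = render_movie(truth, spline_astig, noise=True, seed=8)[0]
        cands = find_peaks(frame - 100.0, spline_astig, [0.0], 6.0, 100.0)
        found = sorted((c.x, c.y) for c in cands)
        assert len(found) == 2
        assert abs(found[0][0] - 25) <= 1 and abs(found[1][0] - 35) <= 1

    def test_empty_z_plane_list_rejected(self, spline_astig):
        with pytest.raises(ValueError):
            find_peaks(np.zeros((32, 32)), spline_astig, [], 6.0, 100.0)


class TestProximityFilter:
    def test_single_localization_unchanged(self):
        kept, dropped = proximity_filter([_Loc(5, 5, 100)], 5.0)
        assert len(kept) == 1 and not dropped

    def test_dimmer_of_close_pair_discarded_and_neighbor_reflagged(self):
        bright = _Loc(10, 10, 200)
        dim = _Loc(12, 10, 100)
        kept, dropped = proximity_filter([bright, dim], 5.0)
        assert dropped == [dim]
        assert kept == [bright]
        assert bright.status == "running"

    def test_equal_heights_discard_the_later_found(self):
        first = _Loc(10, 10, 100)
        second = _Loc(12, 10, 100)
        kept, dropped = proximity_filter([first, second], 5.0)
        assert dropped == [second]
        assert kept == [first]

    def test_distant_pair_untouched(self):
        a, b = _Loc(10, 10, 100), _Loc(30, 30, 200)
        kept, dropped = proximity_filter([a, b], 5.0)
        assert kept == [a, b] and not dropped
        assert a.status == "converged"

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            proximity_filter([], 0.0)


class TestFrameState:
    def test_bookkeeping_conservation_through_model_updates(self):
        rng = np.random.default_rng(0)
        image = rng.poisson(100.0, (32, 32)).astype(float)
        fs = FrameState(image, estimate_background(image))

        class Fake:
            def __init__(self, anchor, roi):
                self.anchor = anchor
                self.roi_model = roi
                self.status = "running"

        a = Fake((4, 6), rng.random((8, 8)) * 50)
        b = Fake((18, 12), rng.random((8, 8)) * 30)
        fs.add_model(a)
        fs.add_model(b)
        assert fs.check_conservation()
        fs.remove_model(a)
        assert fs.check_conservation()
        expected = image - fs.background
        expected[12:20, 18:26] -= b.roi_model
        assert np.allclose(fs.residual, expected, atol=1e-9)


class TestAnalyzeFrame:
    def test_blank_frame_yields_no_localizations(self, spline_astig):
        rng = np.random.default_rng(2)
        frame = rng.poisson(100.0, (64, 64)).astype(float)
        assert analyze_frame(frame, spline_astig, AnalysisConfig()) == []

    def test_isolated_emitters_all_recovered_near_crlb(self, spline_astig):
        truth = uniform_emitters(5, shape=(96, 96), n_frames=1, seed=4,
                                 margin=12, min_separation=18,
                                 photons=4000, background=100, z_range=250)
        frame = render_movie(truth, spline_astig, noise=True, seed=4)[0]
        locs = analyze_frame(frame, spline_astig, AnalysisConfig())
        assert len(locs) == 5
        bound = crlb(spline_astig, 5.5, 5.5, 0.0, 4000.0, 100.0, (12, 12))
        for loc in locs:
            d = np.hypot(truth.x - loc.x, truth.y - loc.y)
            j = int(np.argmin(d))
            assert d[j] * 160.0 < 6.0 * max(bound.x_nm, bound.y_nm) + 2.0
            assert abs(truth.z[j] - loc.z) < 60.0

    def test_engine_is_deterministic(self, spline_astig):
        truth = uniform_emitters(4, shape=(64, 64), n_frames=1, seed=6,
                                 photons=4000, background=100)
        frame = render_movie(truth, spline_astig, noise=True, seed=6)[0]
        first = analyze_frame(frame, spline_astig, AnalysisConfig())
        second = analyze_frame(frame, spline_astig, AnalysisConfig())
        assert [(l.x, l.y, l.z, l.photons) for l in first] == \
               [(l.x, l.y, l.z, l.photons) for l in second]

    def test_close_pair_keeps_only_the_brighter(self, spline_astig):
        from splinepsf.simulate import GroundTruth

        truth = GroundTruth(frame=np.zeros(2, int),
                            x=np.array([30.0, 33.0]), y=np.array([30.0, 30.0]),
                            z=np.zeros(2),
                            photons=np.array([6000.0, 2500.0]),
                            background=100.0, shape=(64, 64), n_frames=1)
        frame = render_movie(truth, spline_astig, noise=True, seed=11)[0]
        locs = analyze_frame(frame, spline_astig, AnalysisConfig())
        xs = sorted(l.x for l in locs)
        # all surviving localizations respect the proximity cutoff
        for i in range(len(xs) - 1):
            assert xs[i + 1] - xs[i] >= 5.0 or len(locs) == 1

    def test_sparse_field_recall_and_false_positives(self, spline_astig):
        """Density 0.03 / um^2 on a 41 x 41 um field: recall >= 95%,
        false positives <= 2%."""
        from splinepsf.io import localizations_to_frame
        from splinepsf.simulate import match_and_score

        truth = uniform_emitters(50, shape=(256, 256), n_frames=1,
                                 z_range=300, photons=4000, background=100,
                                 margin=10, min_separation=10, seed=5)
        frame = render_movie(truth, spline_astig, noise=True, seed=5)[0]
        locs = analyze_frame(frame, spline_astig, AnalysisConfig())
        df = localizations_to_frame(locs, 160.0).rename(
            columns={"x_px": "x", "y_px": "y", "z_nm": "z"})
        res = match_and_score(df, truth)
        assert res["recall"] >= 0.95
        assert res["n_false_positive"] <= 0.02 * truth.x.size
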