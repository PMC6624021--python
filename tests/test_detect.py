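import numpy as np
import pandas as pd
import pytest

from condmotion import detect, synthio
from condmotion.detect import (SCENARIO_DIFFRACTION, SCENARIO_SEGMENTED,
                               SCENARIO_WATERSHED)
from condmotion.stackio import ImageStack
from condmotion.synthio import Spot


def spot_frame(spots, size=96, bg=10.0, noise_sd=0.0, seed=0):
    img = synthio.render_spots((size, size), spots) + bg
    if noise_sd:
        img += np.random.default_rng(seed).normal(0, noise_sd, img.shape)
    return np.clip(img, 0, None)


class TestDriftCorrection:
    def test_zero_drift_recovered_as_zero(self):
        cond, _, _ = synthio.make_invitro_movie(
            4, 64, [Spot(30, 30, 100, 1.0)], noise_sd=0, seed=1)
        _, series = detect.correct_drift(cond, 10)
        assert np.array_equal(series.shifts, np.zeros((4, 2), int))

    def test_imposed_drift_inverted_exactly(self):
        drift = [(0, 0)] + [(3, -2)] * 4
        spots = [Spot(40, 40, 100, 1.0), Spot(80, 60, 90, 1.0),
                 Spot(30, 90, 80, 1.0)]
        cond, _, truth = synthio.make_invitro_movie(
            5, 128, spots, drift=drift, noise_sd=0, seed=3)
        _, series = detect.correct_drift(cond, 10)
        assert np.array_equal(series.shifts, -truth.drift)

    def test_drift_beyond_window_flagged(self):
        drift = [(0, 0), (5, 0)]
        cond, _, _ = synthio.make_invitro_movie(
            2, 64, [Spot(30, 30, 100, 1.0)], drift=drift, noise_sd=0, seed=3)
        _, series = detect.correct_drift(cond, max_shift_px=3)
        assert series.clipped[1]
        assert abs(series.shifts[1]).max() <= 3

    def test_constant_frames_warn_and_zero(self):
        stack = ImageStack(np.full((3, 16, 16), 5.0))
        with pytest.warns(UserWarning, match="constant"):
            _, series = detect.correct_drift(stack, 5)
        assert not series.shifts.any()


class TestDetectFrame:
    def test_single_spot_subpixel_center(self):
        frame = spot_frame([Spot(31.7, 20.3, 50, 1.0)], noise_sd=0.5, seed=2)
        df, labels = detect.detect_frame(frame)
        assert len(df) == 1
        assert df.x.iloc[0] == pytest.approx(31.7, abs=0.5)
        assert df.y.iloc[0] == pytest.approx(20.3, abs=0.5)

    def test_two_separated_spots_are_scenario_one(self):
        frame = spot_frame([Spot(30, 30, 60, 1.0), Spot(40, 30, 60, 1.0)])
        df, _ = detect.detect_frame(frame)
        assert len(df) == 2
        assert set(df.scenario) == {SCENARIO_SEGMENTED}

    def test_blank_frame_no_detections(self):
        df, labels = detect.detect_frame(np.zeros((32, 32)))
        assert len(df) == 0 and labels.max() == 0

    def test_labels_unique_and_area_bounded(self):
        frame = spot_frame([Spot(20, 20, 60, 1.0), Spot(60, 60, 80, 2.5)])
        df, labels = detect.detect_frame(frame)
        ids = np.unique(labels[labels > 0])
        assert sorted(ids) == sorted(df.id)
        assert df.area.sum() <= frame.size
        assert (df.peak >= 0).all()

    def test_translation_equivariance(self):
        spots = [Spot(60, 64, 60, 1.0), Spot(80, 55, 40, 1.0)]
        frame = spot_frame(spots, size=128, bg=0.0)
        df0, _ = detect.detect_frame(frame)
        df1, _ = detect.detect_frame(np.roll(frame, (4, -6), axis=(0, 1)))
        c0 = df0.sort_values("x")[["x", "y"]].to_numpy()
        c1 = df1.sort_values("x")[["x", "y"]].to_numpy()
        assert np.allclose(c1, c0 + np.array([-6.0, 4.0]), atol=1e-6)

    def test_recall_precision_on_noisy_movie(self):
        # SNR >= 5, separations >= 4 px
        rng = np.random.default_rng(6)
        spots = []
        pts = []
        while len(pts) < 12:
            p = rng.uniform(12, 116, 2)
            if all(np.hypot(p[0] - q[0], p[1] - q[1]) >= 8 for q in pts):
                pts.append(p)
        noise_sd = 4.0
        spots = [Spot(float(x), float(y), 10 * noise_sd, 1.0) for x, y in pts]
        tp = fp = fn = 0
        for seed in range(5):
            frame = spot_frame(spots, size=128, bg=10.0, noise_sd=noise_sd,
                               seed=seed)
            df, _ = detect.detect_frame(frame)
            used = set()
            for x, y in pts:
                d = np.hypot(df.x - x, df.y - y)
                d[list(used)] = np.inf
                j = int(np.argmin(d)) if len(d) else -1
                if j >= 0 and d.iloc[j] <= 2.0:
                    tp += 1
                    used.add(j)
                else:
                    fn += 1
            fp += len(df) - len(used)
        recall = tp / (tp + fn)
        precision = tp / (tp + fp)
        assert recall >= 0.95
        assert precision >= 0.95


class TestRatioThreshold:
    @staticmethod
    def iso_frame(peaks, edge_mins):
        return pd.DataFrame({
            "scenario": [SCENARIO_SEGMENTED] * len(peaks),
            "peak": peaks, "edge_min": edge_mins,
        })

    def test_uniform_ratio_distribution_first_percentile(self):
        # ratios exactly linspace(2, 4, 100): 1st pct = 2 + 0.99 * (4-2)/99
        ratios = np.linspace(2, 4, 100)
        df = self.iso_frame(ratios, np.ones(100))
        assert detect.ratio_threshold(df) == pytest.approx(2.02)

    def test_identical_ratios(self):
        df = self.iso_frame(np.full(30, 6.0), np.full(30, 2.0))
        assert detect.ratio_threshold(df) == pytest.approx(3.0)

    def test_too_few_isolated_raises(self):
        df = self.iso_frame([3.0] * 5, [1.0] * 5)
        with pytest.raises(ValueError, match="fallback"):
            detect.ratio_threshold(df, min_isolated=20)


class TestResolveMultimax:
    @staticmethod
    def two_peak_region(valley_depth):
        """Two Gaussian bumps at x=10 and x=22 on one ridge; valley depth
        controlled by a connecting plateau."""
        img = synthio.render_spots(
            (21, 33), [Spot(10, 10, 100, 2.0), Spot(22, 10, 100, 2.0)])
        img += valley_depth * synthio.render_spots(
            (21, 33), [Spot(16, 10, 100, 3.0)])
        mask = img > 15
        maxima = [(10, 10), (10, 22)]
        return img, mask, maxima

    def test_deep_valley_splits_region(self):
        img, mask, maxima = self.two_peak_region(0.0)
        survivors, labels = detect.resolve_multimax(img, mask, maxima, 1.5)
        assert len(survivors) == 2
        assert set(np.unique(labels[mask])) == {1, 2}
        # watershed partitions the region exactly
        assert (labels[mask] > 0).all() and (labels[~mask] == 0).all()

    def test_shallow_valley_merges_discarding_dimmer(self):
        img = synthio.render_spots(
            (21, 33), [Spot(10, 10, 100, 2.0), Spot(22, 10, 90, 2.0)])
        img += 80 * synthio.render_spots((21, 33), [Spot(16, 10, 1.0, 4.0)])
        mask = img > 15
        survivors, labels = detect.resolve_multimax(
            img, mask, [(10, 10), (10, 22)], threshold=5.0)
        assert survivors == [(10, 10)]     # brighter maximum kept
        assert set(np.unique(labels[mask])) == {1}

    def test_single_maximum_identity(self):
        img = synthio.render_spots((21, 21), [Spot(10, 10, 100, 2.0)])
        mask = img > 15
        survivors, labels = detect.resolve_multimax(img, mask, [(10, 10)], 2.0)
        assert survivors == [(10, 10)]
        assert np.array_equal(labels > 0, mask)

    def test_never_increases_maxima(self):
        img, mask, maxima = self.two_peak_region(0.3)
        for thr in (0.5, 2.0, 10.0):
            survivors, _ = detect.resolve_multimax(img, mask, maxima, thr)
            assert 1 <= len(survivors) <= len(maxima)


class TestMaximaOnlyDetection:
    def test_diffraction_limited_disc_area(self):
        frame = spot_frame([Spot(40, 40, 50, 0.46)], size=96)
        df, labels = detect.detect_frame_maxima(frame, psf_sigma_px=0.46)
        assert len(df) == 1
        assert df.scenario.iloc[0] == SCENARIO_DIFFRACTION
        # rasterized 1.4-px-radius disc around the center
        yy, xx = np.mgrid[0:96, 0:96]
        disc = (xx - df.x.iloc[0])**2 + (yy - df.y.iloc[0])**2 <= (3 * 0.46)**2
        assert df.area.iloc[0] == disc.sum()

    def test_stack_detection_counts(self):
        spots = [Spot(20, 20, 80, 1.0), Spot(52, 40, 80, 1.0)]
        stack = ImageStack(np.stack([spot_frame(spots, 64, noise_sd=2.0, seed=s)
                                     for s in range(3)]))
        dets = detect.detect_stack_maxima(stack, psf_sigma_px=1.0)
        assert set(dets.records.frame) == {0, 1, 2}
        assert (dets.records.groupby("frame").size() == 2).all()
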