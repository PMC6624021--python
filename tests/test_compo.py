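import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from condmotion import compo, detect, synthio, trackmotion
from condmotion.compo import (composition_profile, composition_profile_pooled,
                              condensate_content, photobleach_control,
                              select_tracks, track_contents)


def disc_labels(centers, radius, size):
    yy, xx = np.mgrid[0:size, 0:size]
    labels = np.zeros((size, size), int)
    for k, (x, y) in enumerate(centers, start=1):
        labels[(xx - x) ** 2 + (yy - y) ** 2 <= radius**2] = k
    return labels


class TestCondensateContent:
    def test_spot_on_flat_background(self):
        labels = disc_labels([(20, 20)], 3, 48)
        frame = np.where(labels > 0, 100.0, 10.0)
        tab = condensate_content(frame, labels)
        assert tab.content.iloc[0] == pytest.approx(90.0)
        assert tab.bg_mean.iloc[0] == pytest.approx(10.0)
        assert tab.bg_sd.iloc[0] == pytest.approx(0.0)

    def test_uniform_frame_zero_content(self):
        labels = disc_labels([(15, 15), (35, 30)], 3, 48)
        tab = condensate_content(np.full((48, 48), 25.0), labels)
        assert np.allclose(tab.content, 0.0)

    def test_nearby_condensates_share_one_aggregate(self):
        # 3 px apart with 2-px dilation -> masks touch -> one aggregate
        labels = disc_labels([(20, 20), (27, 20)], 2, 48)
        frame = np.full((48, 48), 10.0)
        tab = condensate_content(frame, labels, perimeter_px=2)
        assert tab["aggregate"].nunique() == 1
        assert tab.bg_mean.nunique() == 1
        far = disc_labels([(10, 10), (38, 38)], 2, 48)
        tab2 = condensate_content(frame, far, perimeter_px=2)
        assert tab2["aggregate"].nunique() == 2

    def test_ring_excludes_all_condensate_pixels(self):
        labels = disc_labels([(20, 20), (26, 20)], 2, 48)
        # bright second condensate must not leak into the first one's ring
        frame = np.where(labels == 2, 1000.0, 10.0)
        tab = condensate_content(frame, labels, perimeter_px=2)
        assert tab.bg_mean.iloc[0] == pytest.approx(10.0)

    def test_border_aggregate_flagged_missing(self):
        labels = disc_labels([(1, 1)], 2, 32)
        mask_all = np.ones((32, 32), bool)
        # restrict valid region to the condensate itself: ring empty
        tab = condensate_content(np.full((32, 32), 5.0), labels,
                                 valid_mask=labels > 0)
        assert tab.missing.iloc[0]

    def test_mostly_clipped_mask_missing(self):
        labels = disc_labels([(20, 20)], 3, 48)
        valid = np.zeros((48, 48), bool)
        valid[:, :19] = True   # keeps < half of the disc
        tab = condensate_content(np.full((48, 48), 5.0), labels,
                                 valid_mask=valid)
        assert tab.missing.iloc[0]


def make_filter_fixture():
    """Five hand-built tracks, each violating exactly one selection filter."""
    geom, c, R = _circle_geom()
    frames = np.arange(10)

    def mk(rs, n=10, angle=0.0, wob=0.0):
        rng = np.random.default_rng(1)
        xs = c + np.asarray(rs) * R * np.cos(angle) + rng.normal(0, wob, len(rs))
        ys = c + np.asarray(rs) * R * np.sin(angle) + rng.normal(0, wob, len(rs))
        return trackmotion.Track(frames=np.arange(len(rs)), x=xs, y=ys,
                                 det_ids=np.arange(len(rs)))

    good = mk(np.linspace(0.9, 0.3, 10), wob=0.3)
    short = mk(np.linspace(0.9, 0.3, 4), wob=0.3)            # filter 1
    wobbly = mk([0.8 + 0.02 * ((-1) ** i) for i in range(10)], wob=2.5)  # filter 2
    inside_start = mk(np.linspace(0.5, 0.25, 10), wob=0.3)   # filter 3
    dim = mk(np.linspace(0.9, 0.3, 10), angle=1.5, wob=0.3)  # filter 4
    tracks = [good, short, wobbly, inside_start, dim]

    rows = []
    for ti, tr in enumerate(tracks):
        for f in tr.frames:
            content = 0.5 if ti == 4 else 50.0
            rows.append(dict(track=ti, frame=int(f), det_id=0,
                             content=content, bg_sd=2.0, missing=False))
    contents = pd.DataFrame(rows)
    return tracks, geom, contents


def _circle_geom(radius=100.0, csmac=15.0, size=260):
    from skimage.measure import find_contours

    from condmotion.synapse import SynapseGeometry
    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2.0
    rho = np.hypot(xx - c, yy - c)
    synapse = rho <= radius
    csmac_m = rho <= csmac
    contour = max(find_contours(synapse.astype(float), 0.5), key=len)
    n = 12
    return (SynapseGeometry([synapse] * n, [csmac_m] * n, [(c, c)] * n,
                            [contour] * n), c, radius)


class TestSelectTracks:
    def test_each_filter_rejects_its_violator(self):
        tracks, geom, contents = make_filter_fixture()
        kept, rej = select_tracks(tracks, geom, contents, min_anisotropy=3.0)
        assert kept == [0]
        assert rej == {"duration": 1, "anisotropy": 1, "position": 1,
                       "content": 1}

    def test_four_frame_track_rejected_by_duration(self):
        tracks, geom, contents = make_filter_fixture()
        _, rej = select_tracks([tracks[1]], geom,
                               contents[contents.track == 1].assign(track=0))
        assert rej["duration"] == 1

    def test_generator_tracks_mostly_pass(self, synapse_movie, synapse_pipeline):
        master, slave, truth, geom = synapse_movie
        dets, tracks, m_cont, s_cont = synapse_pipeline
        kept, rej = select_tracks(tracks, geom, s_cont)
        # at least a handful of the 25 designed tracks survive the full
        # detection -> linking -> filtering chain
        assert len(kept) >= 8


class TestCompositionProfile:
    def test_step_decay_recovered(self, synapse_movie, synapse_pipeline, step_g):
        master, slave, truth, geom = synapse_movie
        dets, tracks, m_cont, s_cont = synapse_pipeline
        kept, _ = select_tracks(tracks, geom, s_cont)
        prof = composition_profile(tracks, kept, m_cont, s_cont, geom,
                                   reference_bin=(0.8, 0.9))
        tab = prof.table.set_index("bin_lo")
        for lo in (0.6, 0.7, 0.8):
            if not tab.loc[lo].suppressed:
                assert tab.loc[lo]["median"] == pytest.approx(1.0, abs=0.1)
        for lo in (0.3, 0.4, 0.5):
            if not tab.loc[lo].suppressed:
                assert tab.loc[lo]["median"] == pytest.approx(0.5, abs=0.1)
                assert tab.loc[lo].significant

    def test_gain_invariance_of_normalization(self):
        tracks, geom, contents = make_filter_fixture()
        m = contents[contents.track == 0].copy()
        s = m.copy()
        prof1 = composition_profile([tracks[0]], [0], m, s, geom,
                                    reference_bin=(0.8, 0.9), min_bin_n=1)
        s2 = s.copy()
        s2["content"] = s2.content * 7.0
        prof2 = composition_profile([tracks[0]], [0], m, s2, geom,
                                    reference_bin=(0.8, 0.9), min_bin_n=1)
        pd.testing.assert_frame_equal(prof1.table, prof2.table)

    def test_small_bins_suppressed(self):
        _, geom, _ = make_filter_fixture()
        c = geom.csmac_centers[0][0]
        rs = np.array([0.85, 0.84, 0.83, 0.75, 0.74, 0.65, 0.55, 0.45,
                       0.35, 0.25])
        rng = np.random.default_rng(2)
        tr = trackmotion.Track(frames=np.arange(10), x=c + rs * 100.0,
                               y=c + rng.normal(0, 0.2, 10),
                               det_ids=np.arange(10))
        m = pd.DataFrame(dict(track=0, frame=np.arange(10), det_id=0,
                              content=50.0, bg_sd=2.0, missing=False))
        prof = composition_profile([tr], [0], m, m.copy(), geom,
                                   reference_bin=(0.8, 0.9), min_bin_n=2)
        tab = prof.table.set_index("bin_lo")
        assert tab.loc[0.6].suppressed and tab.loc[0.6].n == 1
        assert np.isnan(tab.loc[0.6]["median"])
        assert not tab.loc[0.8].suppressed

    def test_suppressed_reference_rejected(self):
        tracks, geom, contents = make_filter_fixture()
        m = contents[contents.track == 0].copy()
        with pytest.raises(ValueError, match="reference"):
            composition_profile([tracks[0]], [0], m, m.copy(), geom,
                                reference_bin=(0.8, 0.9), min_bin_n=50)

    def test_notch_ci_brackets_median(self, synapse_movie, synapse_pipeline):
        master, slave, truth, geom = synapse_movie
        dets, tracks, m_cont, s_cont = synapse_pipeline
        kept, _ = select_tracks(tracks, geom, s_cont)
        prof = composition_profile(tracks, kept, m_cont, s_cont, geom,
                                   reference_bin=(0.8, 0.9))
        ok = prof.table[~prof.table.suppressed]
        assert (ok.ci_lo <= ok["median"]).all()
        assert (ok.ci_hi >= ok["median"]).all()

    def test_bonferroni_threshold_in_profile(self, synapse_movie, synapse_pipeline):
        master, slave, truth, geom = synapse_movie
        dets, tracks, m_cont, s_cont = synapse_pipeline
        kept, _ = select_tracks(tracks, geom, s_cont)
        prof = composition_profile(tracks, kept, m_cont, s_cont, geom,
                                   reference_bin=(0.8, 0.9))
        m = sum(1 for _, row in prof.table.iterrows()
                if not row.suppressed
                and (row.bin_lo, row.bin_hi) != prof.reference_bin)
        assert prof.threshold == pytest.approx(0.05 / m)


class TestPhotobleachControl:
    def test_no_bleach_flat_series(self):
        master, slave, truth = synthio.make_synapse_movie(
            15, 50.0, 10.0, 0, bleach_k=0.0, noise_sd=1.0, seed=3)
        from condmotion.synapse import segment_geometry
        geom = segment_geometry(master)
        series = photobleach_control(slave, geom)
        assert np.allclose(series, 1.0, atol=0.02)

    def test_bleach_rate_recovered(self):
        k = 0.01
        master, slave, truth = synthio.make_synapse_movie(
            30, 50.0, 10.0, 0, bleach_k=k, noise_sd=1.0, seed=3)
        from condmotion.synapse import segment_geometry
        geom = segment_geometry(master)
        series = photobleach_control(slave, geom)
        expected = np.exp(-k * np.arange(30))
        assert np.allclose(series, expected, atol=0.02)

    def test_zero_first_frame_rejected(self):
        from condmotion.stackio import ImageStack
        from condmotion.synapse import SynapseGeometry
        mask = np.zeros((16, 16), bool)
        mask[4:12, 4:12] = True
        geom = SynapseGeometry([mask] * 3, [np.zeros_like(mask)] * 3,
                               [(8.0, 8.0)] * 3, [np.empty((0, 2))] * 3)
        frames = np.ones((3, 16, 16))
        frames[0] = 0.0
        with pytest.raises(ValueError, match="first"):
            photobleach_control(ImageStack(frames), geom)
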