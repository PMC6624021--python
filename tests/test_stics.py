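import numpy as np
import pytest
from scipy import stats

from condmotion import stics, synthio
from condmotion.stackio import ImageStack
from condmotion.synthio import FlowSpec


@pytest.fixture(scope="module")
def translation_movie():
    _, actin, _ = synthio.make_invitro_movie(
        18, 128, [], actin_flow=FlowSpec("uniform", vx=1.0, vy=0.0),
        noise_sd=0, seed=7)
    return actin


@pytest.fixture(scope="module")
def translation_field(translation_movie):
    return stics.stics_field(translation_movie)


def interior(vf, size=128, window=16):
    return ((vf.centers[:, 0] >= window) & (vf.centers[:, 0] <= size - window - 1)
            & (vf.centers[:, 1] >= window) & (vf.centers[:, 1] <= size - window - 1))


class TestSticsField:
    def test_static_texture_all_invalid(self):
        _, actin, _ = synthio.make_invitro_movie(12, 96, [], noise_sd=0, seed=7)
        vf = stics.stics_field(actin)
        assert not vf.valid.any()

    def test_uniform_translation_recovered(self, translation_field):
        vf = translation_field
        sel = vf.valid & interior(vf)
        assert sel.sum() == interior(vf).sum()   # every interior subregion valid
        err = np.abs(vf.dxy[sel] - np.array([3.0, 0.0]))
        assert err.max() < 0.1
        assert np.allclose(vf.speed_px_per_frame[sel], 1.0, atol=0.04)

    def test_rotation_equivariance(self, translation_movie, translation_field):
        vf = translation_field
        rot = ImageStack(np.ascontiguousarray(
            np.rot90(translation_movie.frames, k=1, axes=(1, 2))))
        vr = stics.stics_field(rot)
        W = 128
        mapping = {(c[1], W - 1 - c[0]): (d[1], -d[0], v)
                   for c, d, v in zip(vf.centers, vf.dxy, vf.valid)}
        for c, d, v in zip(vr.centers, vr.dxy, vr.valid):
            dy_dx_v = mapping[(c[0], c[1])]
            assert v == dy_dx_v[2]
            if v:
                assert d[0] == pytest.approx(dy_dx_v[0], abs=1e-9)
                assert d[1] == pytest.approx(dy_dx_v[1], abs=1e-9)

    def test_radial_contraction_points_inward(self):
        _, actin, _ = synthio.make_invitro_movie(
            12, 160, [], actin_flow=FlowSpec("radial", center=(79.5, 79.5),
                                             speed=1.0), noise_sd=0, seed=9)
        vf = stics.stics_field(actin)
        rel = vf.centers - np.array([79.5, 79.5])
        rho = np.hypot(rel[:, 0], rel[:, 1])
        def angle_errors(lo, hi):
            sel = vf.valid & (rho > lo) & (rho < hi)
            assert sel.sum() > 10
            inward = -rel[sel] / rho[sel, None]
            v = vf.dxy[sel]
            cosang = (v * inward).sum(1) / np.linalg.norm(v, axis=1)
            return np.degrees(np.arccos(np.clip(cosang, -1, 1)))

        # at one window from the aster the flow direction varies by tens of
        # degrees across the window; the averaged vector is still within 10°
        # except for borderline subregions
        assert np.median(angle_errors(16, 60)) < 5.0
        assert angle_errors(24, 60).max() < 10.0

    def test_window_larger_than_frame_rejected(self):
        stack = ImageStack(np.zeros((5, 8, 8)))
        with pytest.raises(ValueError, match="window"):
            stics.stics_field(stack, window_px=16)

    def test_short_interval_rejected(self, translation_movie):
        with pytest.raises(ValueError, match="shift_frames"):
            stics.stics_field(translation_movie, t_range=(0, 3), shift_frames=3)


def make_field(dxy, valid=None):
    n = len(dxy)
    centers = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
    return stics.VectorField(
        centers=centers, dxy=np.asarray(dxy, float),
        valid=np.ones(n, bool) if valid is None else np.asarray(valid),
        shift_frames=3, frame_interval_s=5.0, pixel_size_um=0.16,
        grid_shape=(n, 1))


class TestCoMovement:
    def test_identical_fields_zero_angles(self):
        vf = make_field([(1.0, 0.0), (0.0, 2.0), (1.0, 1.0)])
        pairs = stics.comovement(vf, vf)
        assert np.allclose(pairs.angle_deg, 0.0, atol=1e-4)
        assert np.allclose(pairs.speed_a, pairs.speed_b)

    def test_rotated_field_ninety_degrees(self):
        a = make_field([(1.0, 0.0), (0.0, 2.0)])
        b = make_field([(0.0, 1.0), (-2.0, 0.0)])
        pairs = stics.comovement(a, b)
        assert np.allclose(pairs.angle_deg, 90.0)

    def test_opposite_vectors_180(self):
        a = make_field([(1.0, 0.0)])
        b = make_field([(-1.0, 0.0)])
        assert stics.comovement(a, b).angle_deg.iloc[0] == pytest.approx(180.0)

    def test_angle_symmetric_in_arguments(self):
        rng = np.random.default_rng(2)
        a = make_field(rng.normal(size=(6, 2)))
        b = make_field(rng.normal(size=(6, 2)))
        assert np.allclose(stics.comovement(a, b).angle_deg,
                           stics.comovement(b, a).angle_deg)

    def test_only_covalid_pairs_emitted(self):
        a = make_field([(1, 0), (1, 0), (1, 0)], valid=[True, False, True])
        b = make_field([(1, 0), (1, 0), (1, 0)], valid=[True, True, False])
        assert len(stics.comovement(a, b)) == 1

    def test_mismatched_grids_rejected(self):
        a = make_field([(1, 0)])
        b = make_field([(1, 0), (0, 1)])
        with pytest.raises(ValueError, match="grid"):
            stics.comovement(a, b)

    def test_speed_histogram_normalized(self):
        h, _, _ = stics.speed_histogram2d([1, 2, 3], [1, 2, 3], bins=5)
        assert h.sum() == pytest.approx(1.0)


class TestRandomizeControl:
    def test_seed_reproducible(self):
        rng = np.random.default_rng(1)
        a = make_field(rng.normal(size=(20, 2)))
        b = make_field(rng.normal(size=(20, 2)))
        p1 = stics.randomize_control(a, b, seed=7)
        p2 = stics.randomize_control(a, b, seed=7)
        assert np.allclose(p1.angle_deg, p2.angle_deg)

    def test_single_subregion_identity(self):
        a = make_field([(1.0, 0.5)])
        b = make_field([(0.5, 1.0)])
        ctrl = stics.randomize_control(a, b, seed=0)
        assert np.allclose(ctrl.angle_deg, stics.comovement(a, b).angle_deg)

    def test_two_subregions_enumerable(self):
        a = make_field([(1.0, 0.0), (0.0, 1.0)])
        b = make_field([(1.0, 0.0), (0.0, 1.0)])
        identity = stics.comovement(a, b).angle_deg.to_numpy()
        swapped = np.array([90.0, 90.0])
        for seed in range(10):
            got = stics.randomize_control(a, b, seed=seed).angle_deg.to_numpy()
            assert np.allclose(got, identity) or np.allclose(got, swapped)

    def test_breaks_alignment_of_identical_fields(self):
        rng = np.random.default_rng(3)
        a = make_field(rng.normal(size=(60, 2)))
        ctrl = stics.randomize_control(a, a, seed=5)
        assert stics.comovement(a, a).angle_deg.mean() < 1e-4
        assert ctrl.angle_deg.mean() > 20.0


class TestSubsampledTest:
    def test_below_trigger_equals_plain_test(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 100), rng.normal(0.2, 1, 100)
        for stat, oracle in [("ks", stats.ks_2samp), ("ranksum", stats.ranksums)]:
            got = stics.subsampled_test(a, b, statistic=stat, seed=1)
            assert got == pytest.approx(oracle(a, b).pvalue)

    def test_identical_large_samples_high_mean_p(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 2000)
        p = stics.subsampled_test(a, a, statistic="ks", seed=2)
        assert p > 0.5

    def test_disjoint_support_tiny_p(self):
        a = np.linspace(0, 1, 2000)
        b = np.linspace(10, 11, 2000)
        assert stics.subsampled_test(a, b, statistic="ks", seed=3) < 1e-6

    def test_unknown_statistic_rejected(self):
        with pytest.raises(ValueError, match="statistic"):
            stics.subsampled_test([1.0], [2.0], statistic="ttest")

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            stics.subsampled_test([], [1.0])
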