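import numpy as np
import pytest

from ecvmap import (
    DeformationField,
    MotionSpec,
    compose_fields,
    fit_map,
    moco_series,
    register_nonrigid,
    simulate_molli_series,
    warp,
)
from ecvmap.phantom import LABEL_MYOCARDIUM, _clean_image

from conftest import anchored_translations


def smooth_test_image(shape=(64, 64), seed=0):
    """Band-limited textured image for warp/registration tests."""
    from scipy.ndimage import gaussian_filter
    rng = np.random.default_rng(seed)
    return gaussian_filter(rng.standard_normal(shape), 4.0)


@pytest.fixture(scope="module")
def phantom_image(mid_spec):
    from ecvmap.phantom import make_phantom_maps
    truth = make_phantom_maps(mid_spec)
    img = _clean_image(truth.proton_density_map, truth.t1_map_pre, 2110.0)
    return img, truth


class TestDeformationField:
    def test_identity_has_zero_displacement(self):
        f = DeformationField.identity((8, 8))
        assert f.max_abs() == 0.0

    def test_nonfinite_rejected(self):
        d = np.zeros((2, 4, 4))
        d[0, 0, 0] = np.inf
        with pytest.raises(ValueError, match="finite"):
            DeformationField(d)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            DeformationField(np.zeros((3, 4, 4)))


class TestWarp:
    def test_identity_field_is_exact(self):
        img = smooth_test_image()
        out = warp(img, DeformationField.identity(img.shape))
        assert np.max(np.abs(out - img)) < 1e-10

    def test_integer_translation_matches_roll(self):
        img = smooth_test_image()
        f = DeformationField.translation(img.shape, 3.0, -2.0)
        out = warp(img, f)
        shifted = np.roll(img, (-3, 2), axis=(0, 1))
        interior = (slice(8, -8), slice(8, -8))
        assert np.max(np.abs(out[interior] - shifted[interior])) < 1e-6

    def test_warp_then_inverse_warp(self):
        img = smooth_test_image()
        from scipy.ndimage import gaussian_filter
        rng = np.random.default_rng(1)
        disp = np.stack([
            gaussian_filter(rng.standard_normal(img.shape), 8.0) * 8
            for _ in range(2)
        ])
        fwd = DeformationField(disp)
        # numerical inverse by fixed-point iteration d_inv = -d(x + d_inv)
        from scipy.ndimage import map_coordinates
        rows, cols = np.mgrid[0:img.shape[0], 0:img.shape[1]]
        inv = np.zeros_like(disp)
        for _ in range(20):
            coords = np.stack([rows + inv[0], cols + inv[1]])
            inv = -np.stack([
                map_coordinates(disp[c], coords, order=1, mode="nearest")
                for c in range(2)
            ])
        back = warp(warp(img, fwd), DeformationField(inv))
        interior = (slice(10, -10), slice(10, -10))
        rms = np.sqrt(np.mean((back[interior] - img[interior]) ** 2))
        assert rms < 0.01 * np.ptp(img)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            warp(np.zeros((4, 4)), DeformationField.identity((5, 5)))


class TestRegisterNonrigid:
    def test_self_registration_near_identity(self, phantom_image):
        img, _ = phantom_image
        f = register_nonrigid(img, img)
        assert np.mean(np.abs(f.displacement)) < 0.05

    def test_known_translation_recovery(self, phantom_image):
        img, truth = phantom_image
        moved = warp(img, DeformationField.translation(img.shape, 3.0, -2.0),
                     interpolation_order=1)
        f = register_nonrigid(moved, img)
        myo = truth.tissue_label_map == LABEL_MYOCARDIUM
        # moved(x) = img(x + t), so the aligning displacement is -t
        assert abs(f.displacement[0][myo].mean() + 3.0) < 0.3
        assert abs(f.displacement[1][myo].mean() - 2.0) < 0.3

    def test_constant_images_identity_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            f = register_nonrigid(np.ones((32, 32)), np.ones((32, 32)))
        assert f.max_abs() == 0.0
        assert f.low_confidence

    def test_pure_noise_bounded(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((48, 48))
        b = rng.standard_normal((48, 48))
        f = register_nonrigid(a, b)
        assert f.max_abs() <= 20.0  # bounded by the safety clip
        assert np.all(np.isfinite(f.displacement))


class TestComposeFields:
    def test_identity_composition(self):
        i1 = DeformationField.identity((16, 16))
        i2 = DeformationField.identity((16, 16))
        assert compose_fields(i1, i2).max_abs() == 0.0

    def test_translations_add_exactly(self):
        t1 = DeformationField.translation((16, 16), 2.0, -1.0)
        t2 = DeformationField.translation((16, 16), -3.0, 4.0)
        c = compose_fields(t1, t2)
        np.testing.assert_allclose(c.displacement[0], -1.0)
        np.testing.assert_allclose(c.displacement[1], 3.0)

    def test_compose_matches_sequential_warp(self):
        from scipy.ndimage import gaussian_filter
        img = smooth_test_image((64, 64), seed=2)
        rng = np.random.default_rng(3)
        fields = []
        for _ in range(2):
            disp = np.stack([
                gaussian_filter(rng.standard_normal(img.shape), 6.0) * 5
                for _ in range(2)
            ])
            fields.append(DeformationField(disp))
        first, second = fields
        sequential = warp(warp(img, first), second)
        composed = warp(img, compose_fields(first, second))
        interior = (slice(8, -8), slice(8, -8))
        rms = np.sqrt(np.mean((sequential[interior] - composed[interior]) ** 2))
        assert rms < 0.01 * np.ptp(img)


@pytest.fixture(scope="module")
def moving_pre(mid_spec, schedule_53):
    motion = MotionSpec(
        per_image_translation=anchored_translations(schedule_53, 4.0, 7)
    )
    series, truth = simulate_molli_series(
        mid_spec, schedule_53, motion, noise_sd=0.01, seed=11
    )
    return series, truth, np.asarray(
        anchored_translations(schedule_53, 4.0, 7))


class TestMocoSeries:
    def test_motion_free_input_unchanged(self, static_series):
        series, _ = static_series
        res = moco_series(series, n_iterations=1)
        for f in res.fields:
            assert f.max_abs() < 0.5
        change = res.corrected.images - series.images
        assert np.sqrt(np.mean(change**2)) < 0.02

    def test_field_recovery_under_half_pixel(self, moving_pre):
        series, truth, tr = moving_pre
        res = moco_series(series)
        myo = truth.tissue_label_map == LABEL_MYOCARDIUM
        for i in range(series.n_images):
            # simulated translation t must be undone by displacement -t
            dy = res.fields[i].displacement[0][myo].mean()
            dx = res.fields[i].displacement[1][myo].mean()
            err = np.hypot(dy + tr[i, 0], dx + tr[i, 1])
            assert err < 0.5, f"image {i}: displacement error {err:.2f} px"

    def test_t1_error_halved_vs_no_moco(self, moving_pre):
        series, truth, _ = moving_pre
        res = moco_series(series)
        no_moco = fit_map(series, signal_floor=0.05)
        myo = truth.tissue_label_map == LABEL_MYOCARDIUM
        err_moco = np.nanmedian(
            np.abs(res.t1.t1_map - truth.t1_map_pre)[myo])
        err_none = np.nanmedian(
            np.abs(no_moco.t1_map - truth.t1_map_pre)[myo])
        assert err_moco < 0.5 * err_none

    def test_rss_decreases_with_moco(self, moving_pre):
        series, truth, _ = moving_pre
        res = moco_series(series)
        no_moco = fit_map(series, signal_floor=0.05)
        myo = truth.tissue_label_map == LABEL_MYOCARDIUM
        assert res.t1.rss_map[myo].sum() < no_moco.rss_map[myo].sum()

    def test_determinism(self, moving_pre):
        series, _, _ = moving_pre
        r1 = moco_series(series, n_iterations=1)
        r2 = moco_series(series, n_iterations=1)
        for f1, f2 in zip(r1.fields, r2.fields):
            assert np.array_equal(f1.displacement, f2.displacement)
        assert np.array_equal(r1.corrected.images, r2.corrected.images)

    def test_single_warp_beats_double_warp(self, mid_spec):
        """Composing fields then warping once preserves resolution better
        than resampling twice (checked against the static truth image)."""
        from ecvmap.phantom import make_phantom_maps
        truth = make_phantom_maps(mid_spec)
        clean = _clean_image(truth.proton_density_map, truth.t1_map_pre,
                             2110.0)
        myo = truth.tissue_label_map == LABEL_MYOCARDIUM
        rng = np.random.default_rng(17)
        wins = 0
        n_trials = 10
        for _ in range(n_trials):
            # odd shifts guarantee the half-warps resample off-grid
            t = rng.choice([-3.0, -1.0, 1.0, 3.0], 2)
            moving = np.roll(clean, (-int(t[0]), -int(t[1])), axis=(0, 1))
            half = DeformationField.translation(clean.shape, -t[0] / 2,
                                                -t[1] / 2)
            single = warp(moving, compose_fields(half, half))
            double = warp(warp(moving, half), half)
            err_single = np.sqrt(np.mean((single[myo] - clean[myo]) ** 2))
            err_double = np.sqrt(np.mean((double[myo] - clean[myo]) ** 2))
            wins += err_single < err_double
        assert wins >= 9, f"single warp won only {wins}/{n_trials} trials"
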