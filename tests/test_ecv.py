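import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecvmap import (
    compute_ecv,
    delta_r1,
    ecv_value,
    fit_map,
    gd_delta_r1,
    normal_range,
    parse_hematocrit,
    partition_coefficient_map,
    segment_blood,
    simulate_study,
)
from ecvmap.ecv import EmptyBloodMaskError
from ecvmap.phantom import LABEL_BLOOD, LABEL_MYOCARDIUM
from ecvmap.t1fit import T1MapResult


def _map_from_t1(t1_map, ok=None):
    t1_map = np.asarray(t1_map, dtype=float)
    ok = np.ones_like(t1_map, dtype=bool) if ok is None else ok
    a = np.ones_like(t1_map)
    return T1MapResult(
        a_map=a, b_map=2 * a, t1_star_map=t1_map.copy(), t1_map=t1_map,
        rss_map=np.zeros_like(t1_map), fit_ok_mask=ok,
    )


@pytest.fixture(scope="module")
def fitted_study(mid_spec, schedule_53):
    pre, post, truth, _ = simulate_study(
        mid_spec, schedule_53, None, None, noise_sd=0.002, seed=5
    )
    pre_t1 = fit_map(pre, signal_floor=0.05)
    post_t1 = fit_map(post, signal_floor=0.05)
    return pre_t1, post_t1, truth, mid_spec


class TestDeltaR1:
    def test_worked_example(self):
        assert delta_r1(1500, 300) == pytest.approx(0.00266667, abs=1e-8)

    def test_no_change_is_zero(self):
        assert delta_r1(1234.5, 1234.5) == 0.0

    def test_second_example(self):
        assert delta_r1(1000, 450) == pytest.approx(0.00122222, abs=1e-8)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            delta_r1(-1500, 300)


class TestGdDeltaR1:
    def test_unit_concentration(self):
        assert gd_delta_r1(1.0) == 4.5

    def test_zero(self):
        assert gd_delta_r1(0.0) == 0.0

    def test_linearity(self):
        assert gd_delta_r1(0.5) == pytest.approx(2.25)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            gd_delta_r1(-0.1)


class TestNormalRange:
    def test_published_cohort_numbers(self):
        low, high = normal_range(25.4, 2.5)
        assert low == pytest.approx(20.4)
        assert high == pytest.approx(30.4)

    def test_zero_sd(self):
        assert normal_range(30.0, 0.0) == (30.0, 30.0)

    def test_arithmetic(self):
        assert normal_range(30, 4) == (22, 38)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            normal_range(25.0, -1.0)


class TestParseHematocrit:
    @pytest.mark.parametrize("raw,expected", [
        (0.42, 0.42), (42, 0.42), ("42%", 0.42), ("0.42", 0.42), ("42", 0.42),
    ])
    def test_accepted_forms(self, raw, expected):
        assert parse_hematocrit(raw) == pytest.approx(expected)

    @pytest.mark.parametrize("raw", [0.0, -3, "150%", 100])
    def test_rejected(self, raw):
        with pytest.raises(ValueError):
            parse_hematocrit(raw)


class TestSegmentBlood:
    def test_phantom_mask_inside_blood_label(self, fitted_study):
        pre_t1, post_t1, truth, spec = fitted_study
        blood = segment_blood(pre_t1, post_t1)
        assert np.all(truth.tissue_label_map[blood.mask] == LABEL_BLOOD)
        assert blood.t1_blood_pre == pytest.approx(spec.t1_blood_pre, abs=5)
        assert blood.t1_blood_post == pytest.approx(spec.t1_blood_post, abs=5)

    def test_uniform_map_empty_mask_error(self):
        res = _map_from_t1(np.full((32, 32), 1000.0))
        with pytest.raises(EmptyBloodMaskError):
            segment_blood(res)

    def test_single_suprathreshold_pixel_removed(self):
        t1 = np.full((32, 32), 1000.0)
        t1[10, 10] = 1600.0
        with pytest.raises(EmptyBloodMaskError):
            segment_blood(_map_from_t1(t1))

    def test_threshold_strictly_greater(self):
        t1 = np.full((32, 32), 1250.0)  # exactly at threshold: excluded
        with pytest.raises(EmptyBloodMaskError):
            segment_blood(_map_from_t1(t1))

    def test_erosion_removes_boundary(self):
        t1 = np.full((32, 32), 1000.0)
        t1[8:24, 8:24] = 1500.0
        blood = segment_blood(_map_from_t1(t1))
        border = np.zeros_like(t1, dtype=bool)
        border[8, 8:24] = border[23, 8:24] = True
        border[8:24, 8] = border[8:24, 23] = True
        assert not blood.mask[border].any()


class TestComputeEcv:
    def test_worked_example_pixel(self):
        # (1000 -> 450), blood (1500 -> 300), hct 0.42 -> 26.6%
        val = 100 * ecv_value(1000, 450, 1500, 300, 0.42)
        assert val == pytest.approx(26.576, abs=0.01)
        assert round(val, 1) == 26.6

    def test_no_t1_change_gives_zero(self):
        assert ecv_value(1000, 1000, 1500, 300, 0.42) == 0.0

    def test_blood_pixels_evaluate_to_blood_ecv(self, fitted_study):
        pre_t1, post_t1, truth, spec = fitted_study
        blood = segment_blood(pre_t1, post_t1)
        emap = compute_ecv(pre_t1, post_t1, blood, spec.hematocrit)
        inner_blood = blood.mask
        med = np.nanmedian(emap.ecv_raw[inner_blood])
        assert med == pytest.approx((1 - spec.hematocrit) * 100, abs=1.0)

    def test_myocardium_recovers_simulated_ecv(self, fitted_study):
        pre_t1, post_t1, truth, spec = fitted_study
        blood = segment_blood(pre_t1, post_t1)
        emap = compute_ecv(pre_t1, post_t1, blood, spec.hematocrit)
        from skimage.morphology import disk, erosion
        myo = erosion(truth.tissue_label_map == LABEL_MYOCARDIUM, disk(2))
        med = np.nanmedian(emap.ecv_raw[myo])
        assert med == pytest.approx(spec.ecv_myo * 100, abs=0.5)

    def test_mislabelled_series_hard_error(self):
        pre = _map_from_t1(np.full((16, 16), 300.0))
        post = _map_from_t1(np.full((16, 16), 1500.0))
        from ecvmap.ecv import BloodMask
        blood = BloodMask(
            mask=np.ones((16, 16), bool), t1_blood_pre=300.0,
            t1_blood_post=1500.0, n_pixels=256, threshold_used=1250.0,
            erosion_radius=1, min_component=10,
        )
        with pytest.raises(ValueError, match="mislabelled"):
            compute_ecv(pre, post, blood, 0.42)

    def test_negative_raw_marked_invalid_and_retained(self):
        pre = _map_from_t1(np.full((4, 4), 1000.0))
        post_vals = np.full((4, 4), 450.0)
        post_vals[0, 0] = 1100.0  # dR1 < 0 at this pixel
        post = _map_from_t1(post_vals)
        from ecvmap.ecv import BloodMask
        blood = BloodMask(
            mask=np.zeros((4, 4), bool), t1_blood_pre=1500.0,
            t1_blood_post=300.0, n_pixels=0, threshold_used=1250.0,
            erosion_radius=1, min_component=10,
        )
        emap = compute_ecv(pre, post, blood, 0.42)
        assert not emap.valid_mask[0, 0]
        assert emap.ecv_raw[0, 0] < 0
        assert np.isnan(emap.ecv[0, 0])

    @given(
        hct_a=st.floats(0.2, 0.6), hct_b=st.floats(0.2, 0.6),
    )
    @settings(max_examples=25, deadline=None)
    def test_hematocrit_linearity(self, hct_a, hct_b):
        pre = _map_from_t1(np.full((4, 4), 1000.0))
        post = _map_from_t1(np.full((4, 4), 450.0))
        from ecvmap.ecv import BloodMask
        blood = BloodMask(
            mask=np.zeros((4, 4), bool), t1_blood_pre=1500.0,
            t1_blood_post=300.0, n_pixels=0, threshold_used=1250.0,
            erosion_radius=1, min_component=10,
        )
        ea = compute_ecv(pre, post, blood, hct_a)
        eb = compute_ecv(pre, post, blood, hct_b)
        ratio = (1 - hct_a) / (1 - hct_b)
        np.testing.assert_allclose(ea.ecv_raw, eb.ecv_raw * ratio, rtol=1e-12)


class TestPartitionCoefficient:
    def _setup(self):
        pre = _map_from_t1(np.full((4, 4), 1000.0))
        post = _map_from_t1(np.full((4, 4), 450.0))
        from ecvmap.ecv import BloodMask
        blood = BloodMask(
            mask=np.zeros((4, 4), bool), t1_blood_pre=1500.0,
            t1_blood_post=300.0, n_pixels=0, threshold_used=1250.0,
            erosion_radius=1, min_component=10,
        )
        return pre, post, blood

    def test_worked_example(self):
        pre, post, blood = self._setup()
        lam = partition_coefficient_map(pre, post, blood)
        assert lam[0, 0] == pytest.approx(0.4583, abs=1e-4)

    def test_blood_pixel_lambda_one(self):
        pre, post, blood = self._setup()
        pre.t1_map[:] = 1500.0
        post.t1_map[:] = 300.0
        lam = partition_coefficient_map(pre, post, blood)
        np.testing.assert_allclose(lam, 1.0, rtol=1e-12)

    def test_ecv_lambda_identity(self):
        pre, post, blood = self._setup()
        hct = 0.37
        lam = partition_coefficient_map(pre, post, blood)
        emap = compute_ecv(pre, post, blood, hct)
        np.testing.assert_allclose(
            emap.ecv_raw, (1 - hct) * lam * 100.0, rtol=1e-12
        )
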