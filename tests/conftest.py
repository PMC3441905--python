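import numpy as np
import pytest

from ecvmap import (
    MotionSpec,
    PhantomSpec,
    build_ti_schedule,
    make_phantom_maps,
    simulate_molli_series,
    simulate_study,
)


@pytest.fixture(scope="session")
def schedule_53():
    return build_ti_schedule("5-3", heart_rate=60, ti_min=110, ti_increment=80)


@pytest.fixture(scope="session")
def schedule_35():
    return build_ti_schedule("3-5", heart_rate=60, ti_min=110, ti_increment=80)


@pytest.fixture(scope="session")
def small_spec():
    """64x64 phantom used by fast unit tests."""
    return PhantomSpec(
        grid_shape=(64, 64),
        blood_radius=10,
        myo_inner_radius=14,
        myo_outer_radius=24,
    )


@pytest.fixture(scope="session")
def mid_spec():
    """96x96 phantom used by registration/pipeline tests."""
    return PhantomSpec(
        grid_shape=(96, 96),
        blood_radius=14,
        myo_inner_radius=19,
        myo_outer_radius=30,
    )


@pytest.fixture(scope="session")
def small_truth(small_spec):
    return make_phantom_maps(small_spec)


@pytest.fixture(scope="session")
def static_series(small_spec, schedule_53):
    """Noiseless motion-free pre-contrast series with its ground truth."""
    return simulate_molli_series(small_spec, schedule_53, noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def noisy_series(small_spec, schedule_53):
    """Motion-free series with 1%-of-A Gaussian noise (seeded)."""
    return simulate_molli_series(small_spec, schedule_53, noise_sd=0.01, seed=2)


def anchored_translations(schedule, max_px, seed):
    """Random per-image translations, zero at the longest-TI anchor."""
    rng = np.random.default_rng(seed)
    tr = np.round(rng.uniform(-max_px, max_px, (len(schedule.ti_values), 2)), 1)
    tr[int(np.argmax(schedule.ti_values))] = 0.0
    return tuple(map(tuple, tr))


@pytest.fixture(scope="session")
def moving_study(mid_spec, schedule_53):
    """Seeded noisy study: per-image motion plus a 5 px inter-series shift."""
    anchor = int(np.argmax(schedule_53.ti_values))
    m_pre = MotionSpec(
        per_image_translation=anchored_translations(schedule_53, 4.0, 7)
    )
    m_post = MotionSpec(
        per_image_translation=anchored_translations(schedule_53, 4.0, 8),
        bulk_shift=(5.0, 0.0),
        anchor_index=anchor,
    )
    pre, post, truth_pre, truth_post = simulate_study(
        mid_spec, schedule_53, m_pre, m_post, noise_sd=0.01, seed=11
    )
    return dict(
        pre=pre, post=post, truth_pre=truth_pre, truth_post=truth_post,
        spec=mid_spec,
    )
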