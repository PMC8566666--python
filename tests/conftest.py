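import numpy as np
import pytest

from fgdn import SyntheticSpec, TrainConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small well-separated 2-class, 3-site cohort for pipeline tests."""
    spec = SyntheticSpec(n_subjects_per_class=30, n_rois=8, n_timepoints=120,
                         signal_regions=(1, 4, 6), effect_size=0.5, seed=42)
    cohort, gt = generate_cohort(spec)
    return cohort, gt


@pytest.fixture
def fast_cfg():
    """A reduced-width config that keeps unit tests quick."""
    return TrainConfig(seed=7, channels=8, hidden=16, max_epochs=80, patience=15,
                       learning_rate=5e-4)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_spd(n, rng, scale=1.0):
    a = rng.standard_normal((n, n))
    return scale * (a @ a.T / n + np.eye(n))
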