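import numpy as np
import pytest

from ftirnet import (
    PreprocessConfig,
    RawSpectrum,
    SimConfig,
    default_library,
    generate_dataset,
    preprocess_batch,
)


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def small_cohort():
    """200 simulated samples, labels table, and their feature matrix."""
    cfg = SimConfig(n_samples=200, seed=42)
    samples, table = generate_dataset(cfg)
    features, rejections = preprocess_batch(
        [s.spectrum for s in samples], PreprocessConfig()
    )
    assert not rejections
    X = np.vstack([f.values for f in features])
    return samples, table, X


def make_spectrum(n_points=1700, lo=600.0, hi=3800.0, fn=None, seed=0, jitter=True):
    """A spectrum sampled on an (optionally irregular) grid covering [lo, hi]."""
    rng = np.random.default_rng(seed)
    x = np.linspace(lo, hi, n_points)
    if jitter:
        step = (hi - lo) / (n_points - 1)
        x[1:-1] += rng.uniform(-0.3 * step, 0.3 * step, size=n_points - 2)
        x.sort()
    y = fn(x) if fn is not None else 0.2 + 0.1 * np.sin(x / 150.0) + 0.05 * rng.random(n_points)
    return RawSpectrum(sample_id="syn", wavenumbers=x, absorbances=y)
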