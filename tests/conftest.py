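import numpy as np
import pytest

from spectroscreen import Spectrum, SyntheticConfig, WavenumberAxis, generate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def axis64():
    """Descending 64-point axis, 4 cm^-1 spacing."""
    return WavenumberAxis(np.linspace(1800.0, 1548.0, 64))


@pytest.fixture
def random_spectrum(rng, axis64):
    return Spectrum(axis64, rng.uniform(0.1, 1.0, 64), subject_id="s1")


@pytest.fixture
def small_cohort():
    """Tiny default-structure cohort: 4 vs 6 subjects, 3 replicates."""
    cfg = SyntheticConfig(n_nd=4, n_t2d=6, seed=7)
    return generate(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size default cohort (23 vs 45 x 3 replicates), shared."""
    return generate(SyntheticConfig(seed=11))


def brute_force_lower_hull(x, y):
    """O(n^2)-per-point reference rubberband baseline: at each abscissa
    the minimum over all point-pair segments spanning it."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    base = np.full(n, np.inf)
    for j in range(n):
        for k in range(j + 1, n):
            span = (x >= x[j]) & (x <= x[k])
            t = (x[span] - x[j]) / (x[k] - x[j])
            base[span] = np.minimum(base[span], y[j] + t * (y[k] - y[j]))
    return base


def brute_force_auc(values, labels_positive):
    """Pairwise Mann-Whitney probability, ties counted one half."""
    pos = np.asarray(values, float)[np.asarray(labels_positive, bool)]
    neg = np.asarray(values, float)[~np.asarray(labels_positive, bool)]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))
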