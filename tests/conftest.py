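import numpy as np
import pytest

from yieldtrends import YieldSeries


def make_series(values, first_year=1961, unit_id="U"):
    values = np.asarray(values, dtype=float)
    years = np.arange(first_year, first_year + values.size)
    return YieldSeries(unit_id, years, values)


@pytest.fixture
def linear_series():
    """Exact line y = 2.0 + 0.1·T, M = 10 (T is 1-based)."""
    t = np.arange(1, 11)
    return make_series(2.0 + 0.1 * t)


@pytest.fixture
def long_linear_series():
    """Exact line over 50 years, France-like slope."""
    t = np.arange(1, 51)
    return make_series(2.5 + 0.13 * t)


@pytest.fixture
def noisy_series():
    """Seeded noisy upward trend, M = 40."""
    rng = np.random.default_rng(11)
    t = np.arange(1, 41)
    return make_series(np.abs(2.0 + 0.08 * t + rng.normal(0, 0.3, 40)) + 0.2)
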