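import numpy as np
import pytest

from meiomap.profiles import StrandProfile
from meiomap.synthetic import GeneratorConfig, OffsetModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A fast generator configuration for unit tests."""
    return GeneratorConfig(n_hotspots=50, n_cells=3, pairs_per_cell=40,
                           outcome_events_per_hotspot=4.0, seed=7)


@pytest.fixture
def point_mass_offsets():
    return OffsetModel(sd=0.0)


def make_profile(crick, watson=None, bin_width=20):
    crick = np.asarray(crick, dtype=float)
    watson = crick[::-1].copy() if watson is None else np.asarray(watson, float)
    return StrandProfile(crick, watson, bin_width=bin_width)


@pytest.fixture
def symmetric_profile():
    """Symmetric unimodal coverage on a ±6000 bp grid."""
    m = 300
    x = np.arange(-m, m + 1) * 20.0
    crick = np.exp(-0.5 * (x / 400.0) ** 2) * 100.0
    return make_profile(crick, crick.copy())
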