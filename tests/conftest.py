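import numpy as np
import pytest

from relomics.preprocess import QuantizedROI


@pytest.fixture
def make_roi():
    """Build a QuantizedROI from an integer level map (0 = outside)."""

    def _make(levels, ng=None, spacing=1.0):
        levels = np.asarray(levels, dtype=np.int32)
        mask = levels > 0
        ng = ng or int(levels.max())
        return QuantizedROI(
            levels, mask, ng, np.arange(1, ng + 1, dtype=float), spacing
        )

    return _make


@pytest.fixture
def small_phantom_spec():
    """A reduced two-repeat phantom for fast end-to-end tests."""
    from relomics.phantom import PhantomSpec

    return PhantomSpec(n_repeats=2, seed=11)


@pytest.fixture(scope="session")
def default_cohort():
    from relomics.cohort import CohortGenConfig, generate_cohort

    return generate_cohort(CohortGenConfig(seed=7))
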