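import numpy as np
import pytest

from tempsf.sfcore import ScaleRange, StructureFunction


@pytest.fixture
def make_sf():
    """Build a StructureFunction directly from values on taus 1..len(values)."""

    def _make(values, order=1.0, normalized=True, n=10_000):
        values = np.asarray(values, dtype=float)
        taus = np.arange(1, values.size + 1)
        return StructureFunction(taus=taus, values=values, order=order,
                                 normalized=normalized, n_diffs=n - taus)

    return _make


@pytest.fixture
def full_scales():
    return ScaleRange(1, 1000)
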