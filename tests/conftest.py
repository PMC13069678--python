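import numpy as np
import pytest

from chronet import Region, SampleMeta, SignalMatrix


def make_signal(values, time_points=None, replicates=None, batches=None, chroms=None):
    """Wrap a plain array as a SignalMatrix with generated regions/samples."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    chroms = chroms or ["chr1"] * n
    regions = [Region(chroms[i], i * 1000, i * 1000 + 500) for i in range(n)]
    time_points = time_points if time_points is not None else list(range(m))
    replicates = replicates or ["1"] * m
    batches = batches or [None] * m
    samples = [
        SampleMeta(f"s{j}", float(time_points[j]), str(replicates[j]), batches[j])
        for j in range(m)
    ]
    return SignalMatrix(regions=regions, samples=samples, values=values)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_signal(rng):
    """200 regions x 8 samples of continuous signal (no ties)."""
    return make_signal(rng.normal(size=(200, 8)))
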