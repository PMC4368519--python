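import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(987123)


def integer_partitions(n, max_part=None):
    """All partitions of ``n`` as descending tuples (exhaustive oracle)."""
    if n == 0:
        yield ()
        return
    if max_part is None:
        max_part = n
    for k in range(min(n, max_part), 0, -1):
        for rest in integer_partitions(n - k, k):
            yield (k,) + rest


def shannon(counts):
    counts = np.asarray(counts, dtype=float)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())
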