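import numpy as np
import pandas as pd
import pytest

from compactnmf.encoding import FeatureMatrix


def make_feature_matrix(values, probe_index=None, chrom="chr1", channel="loss", samples=None):
    """FeatureMatrix over a single (channel, chromosome) block unless overridden."""
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    if probe_index is None:
        probe_index = np.arange(n)
    meta = pd.DataFrame(
        {
            "probe": [f"p{j}" for j in range(n)],
            "chrom": [chrom] * n if isinstance(chrom, str) else list(chrom),
            "position": (np.asarray(probe_index) + 1) * 1000,
            "probe_index": probe_index,
            "channel": [channel] * n if isinstance(channel, str) else list(channel),
        }
    )
    if samples is None:
        samples = [f"S{i}" for i in range(values.shape[0])]
    return FeatureMatrix(values=values, feature_meta=meta, samples=samples)


@pytest.fixture
def rng():
    return np.random.default_rng(20130719)


@pytest.fixture
def duplicated_matrix(rng):
    """Random non-negative matrix whose columns come in duplicated runs."""
    m, groups = 12, 6
    reps = rng.integers(1, 4, size=groups)
    base = rng.integers(0, 3, size=(m, groups)).astype(float)
    cols = np.hstack([np.tile(base[:, [g]], (1, reps[g])) for g in range(groups)])
    return make_feature_matrix(cols)
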