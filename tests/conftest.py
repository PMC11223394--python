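import numpy as np
import pytest

from methyltoo.constants import ALL_CLASSES
from methyltoo.io import MethylCallRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_calls(triples, chrom="sim"):
    """Build call records from (read_id, pos, meth) triples."""
    return [MethylCallRecord(r, chrom, p, bool(m)) for r, p, m in triples]


@pytest.fixture
def random_atlas(rng):
    """Well-conditioned random 6 x 50 atlas for deconvolution tests."""
    from methyltoo.atlas import AtlasMatrix

    values = rng.uniform(0.05, 0.95, size=(6, 50))
    return AtlasMatrix(
        class_labels=list(ALL_CLASSES),
        region_ids=[f"r{j:06d}" for j in range(50)],
        values=values,
    )


def make_cluster_dataset(seed=0, n_per_class=100, n_classes=5, d=8, separation=3.0,
                         test_fraction=0.2):
    """Gaussian class clusters separated by `separation` x the within-class
    deviation magnitude (sigma * sqrt(d) for isotropic unit-sd noise);
    returns features, labels, and a test mask."""
    rng = np.random.default_rng(seed)
    # orthogonal one-hot means scaled so pairwise distance = separation * sqrt(d)
    scale = separation * np.sqrt(d) / np.sqrt(2.0)
    means = np.zeros((n_classes, d))
    for c in range(n_classes):
        means[c, c % d] = scale
    x = np.vstack([rng.normal(means[c], 1.0, (n_per_class, d)) for c in range(n_classes)])
    y = np.repeat(np.arange(n_classes), n_per_class)
    perm = rng.permutation(len(y))
    x, y = x[perm], y[perm]
    n_test = int(test_fraction * len(y))
    test_mask = np.zeros(len(y), dtype=bool)
    test_mask[rng.choice(len(y), n_test, replace=False)] = True
    return x, y, test_mask
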