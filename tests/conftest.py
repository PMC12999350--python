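import numpy as np
import pytest

import smibench as sb


@pytest.fixture
def tiny_matrix() -> sb.SpatialMatrix:
    """4 spots x 3 metabolites with one missing cell."""
    x = np.array(
        [
            [1.0, 2.0, 3.0],
            [4.0, np.nan, 6.0],
            [7.0, 8.0, 9.0],
            [2.0, 4.0, 1.0],
        ]
    )
    coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    return sb.SpatialMatrix(x, coords, ["a", "b", "c", "d"], ["m1", "m2", "m3"])


@pytest.fixture(scope="session")
def smooth_fixture():
    """The default synthetic fixture: 40x40 grid, 60 metabolites, smoothness 3."""
    m, labels = sb.generate_dataset(sb.SyntheticSpec())
    return m, labels


@pytest.fixture(scope="session")
def accuracy_track(smooth_fixture):
    """Accuracy-track input: zeros treated as missing, <10%-missing columns."""
    m, _ = smooth_fixture
    return sb.filter_for_accuracy(sb.drop_empty_spots(sb.zeros_to_missing(m)))


@pytest.fixture(scope="session")
def masked_mcar30(accuracy_track) -> sb.MaskedDataset:
    """30% MCAR dropout on the smooth fixture's accuracy track."""
    return sb.mask_mcar(accuracy_track, 0.3, seed=1)


def random_masked(n=20, p=8, frac=0.25, seed=0) -> sb.MaskedDataset:
    """Small random benchmark instance for metric and contract tests."""
    rng = np.random.default_rng(seed)
    x = rng.gamma(2.0, 3.0, size=(n, p))
    m = sb.SpatialMatrix(x, rng.uniform(0, 10, size=(n, 2)))
    return sb.mask_mcar(m, frac, seed=seed)
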