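import numpy as np
import pytest

from l1kpeaks.io import BeadVector, ColorGroup


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_group(
    rng,
    m=3,
    n_hi=40,
    n_lo=20,
    mu_high=8.0,
    mu_low=6.0,
    sd=0.2,
    color_id="c0",
    outliers=(),
):
    """Two-peak replicate group with optional extra beads appended to sample 0."""
    vecs = []
    for i in range(m):
        x = np.concatenate(
            [
                rng.normal(mu_high, sd, size=n_hi),
                rng.normal(mu_low, sd, size=n_lo),
                np.asarray(outliers, dtype=float) if i == 0 else np.empty(0),
            ]
        )
        vecs.append(BeadVector(f"s{i}", color_id, x))
    return ColorGroup(color_id, tuple(vecs))


@pytest.fixture
def two_peak_group(rng):
    return make_group(rng)
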