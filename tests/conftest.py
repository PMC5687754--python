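import numpy as np
import pytest

from omicspls import SimConfig, gen_multiblock, gen_multistudy, gen_single


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_single():
    """Well-separated 3-class single block (45 x 40, 12 markers)."""
    block, y, truth = gen_single(SimConfig(
        n_per_class=15, p=40, k=3, n_informative=12, effect=3.0, seed=7))
    return block, y, truth


@pytest.fixture
def small_multiblock():
    blocks, y, truth = gen_multiblock(SimConfig(
        n_per_class=20, p=(30, 25), k=3, n_informative=(8, 8),
        factor_strength=0.85, seed=11))
    return blocks, y, truth


@pytest.fixture
def small_multistudy():
    block, y, study, truth = gen_multistudy(SimConfig(
        n_per_class=16, p=60, k=3, n_informative=12, effect=2.0,
        n_studies=4, study_offset=2.0, study_scale=0.2, seed=13))
    return block, y, study, truth


def align_sign(a, ref):
    """Flip columns of ``a`` to match the sign of ``ref`` (for comparing
    solutions defined up to sign)."""
    a = np.array(a, dtype=float, copy=True)
    for h in range(a.shape[1]):
        j = np.argmax(np.abs(ref[:, h]))
        if a[j, h] * ref[j, h] < 0:
            a[:, h] *= -1
    return a
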