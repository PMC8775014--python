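import numpy as np
import pytest

from pmmcodec import examples as ex
from pmmcodec.model import ModelSpec
from pmmcodec.simulate import ScenarioSpec, random_pmm, sample_sequence


@pytest.fixture
def abc_alphabet():
    return ex.ABC


@pytest.fixture
def message():
    return ex.MESSAGE


@pytest.fixture
def cond_probs_abc():
    return ex.conditional_probs_abc()


@pytest.fixture
def three_part_partition():
    return ex.three_part_partition()


@pytest.fixture
def binary_counts():
    return ex.binary_order3_counts()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_sample(alphabet_size, order, n_parts, n, seed, separation=0.0, block_size=4):
    """Random PMM + sample of length n, fully seeded."""
    scenario = ScenarioSpec(
        label=f"fx{seed}",
        alphabet_size=alphabet_size,
        order=order,
        n_parts=n_parts,
        separation=separation,
        block_size=block_size,
    )
    gen = np.random.default_rng(seed)
    pmm = random_pmm(scenario, gen)
    seq = sample_sequence(pmm, n, gen)
    return scenario, pmm, seq


@pytest.fixture
def small_sample():
    scenario, pmm, seq = make_sample(3, 2, 3, 2000, seed=11, separation=0.3)
    return scenario, pmm, seq, ModelSpec(order=2, block_size=4)
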