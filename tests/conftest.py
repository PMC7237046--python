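import itertools
import math

import numpy as np
import pytest

from snpfold.binding import AffinityTable
from snpfold.fold import BASES, EnergyModel


@pytest.fixture(scope="session")
def model():
    return EnergyModel()


@pytest.fixture(scope="session")
def stack_model():
    return EnergyModel(stack_bonus=-1.5)


def random_rna(rng, length):
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def make_table(k, fill=math.inf, special=None):
    """Complete k-mer table with a constant fill and optional overrides."""
    kd = {"".join(t): fill for t in itertools.product(BASES, repeat=k)}
    if special:
        kd.update(special)
    return AffinityTable(kd, k=k)


@pytest.fixture(scope="session")
def table3(request):
    """Complete random k=3 table spanning ~2 decades, deterministic."""
    rng = np.random.default_rng(12345)
    kd = {
        "".join(t): float(10 ** rng.uniform(0, 2))
        for t in itertools.product(BASES, repeat=3)
    }
    return AffinityTable(kd, k=3)
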