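import numpy as np
import pytest

from kinfer.inference import ConditionVector
from kinfer.network import KinaseSubstrateNetwork, KSInteraction


def make_cv(fc, condition="c1"):
    fc = np.asarray(fc, dtype=float)
    keys = [(f"P{i:04d}", 8, "S") for i in range(fc.size)]
    return ConditionVector(site_keys=keys, fc=fc, condition_id=condition)


def regulon_of(indices):
    return [(f"P{i:04d}", 8) for i in indices]


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def toy_network():
    """Two kinases: A with 3 substrates, B with 7, one shared site."""
    ints = []
    for i in (0, 1, 2):
        ints.append(KSInteraction("A", f"P{i:04d}", 8, "S"))
    for i in (2, 3, 4, 5, 6, 7, 8):
        ints.append(KSInteraction("B", f"P{i:04d}", 8, "S"))
    return KinaseSubstrateNetwork(ints)
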