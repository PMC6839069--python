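import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")

from clonalmix import PRIVATE, SHARED, CasePair, ModelParams, MutationLocus


def make_case(case_id="c", shared_ps=(), private_ps=()):
    loci = [
        MutationLocus(f"s{i}", p, SHARED) for i, p in enumerate(shared_ps)
    ] + [
        MutationLocus(f"p{i}", p, PRIVATE) for i, p in enumerate(private_ps)
    ]
    return CasePair(case_id, loci)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def scenario2_params():
    return ModelParams(pi=0.25, mu=-1.0, sigma=1.0)


@pytest.fixture
def mixed_case():
    """One shared rare locus, a handful of private loci."""
    return make_case("mix", shared_ps=(0.001,), private_ps=(0.01, 0.137, 0.001))
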