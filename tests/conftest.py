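import numpy as np
import pytest
from hypothesis import settings

from dockrank import RankedList

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_permutation_list(rng, n, name="L", items=None):
    items = items or [f"m{i:02d}" for i in range(n)]
    order = rng.permutation(len(items))
    return RankedList(name=name, items=tuple(np.asarray(items)[order]))
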