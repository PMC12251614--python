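import numpy as np
import pytest

import combsim as cs


@pytest.fixture(scope="session")
def default_table():
    return cs.PairTable.default()


@pytest.fixture(scope="session")
def fene():
    return cs.FENEParams()


@pytest.fixture(scope="session")
def small_comb():
    """A8(B1)2 — the vesicle-forming molecule."""
    return cs.make_topology(8, 1, 2, seed=1)


@pytest.fixture(scope="session")
def packed_state(small_comb):
    """Small packed box reused across read-only tests."""
    return cs.pack_box(
        small_comb,
        cs.PackingSpec(box=(10.0, 10.0, 10.0), phi=0.15, placement_seed=3),
    )


def random_comb_state(n_beads=20, seed=0, box=20.0):
    """A random self-avoiding comb conformation in a periodic box."""
    from combsim.builder import _grow_chain

    rng = np.random.default_rng(seed)
    top = cs.make_topology(8, 2, 3, seed=seed)
    pos = _grow_chain(top, rng)[:n_beads] if n_beads < top.n_beads else _grow_chain(top, rng)
    boxv = np.array([box] * 3)
    return pos + box / 2, top, boxv
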