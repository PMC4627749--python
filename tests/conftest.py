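import random

import pytest

from demetech.dynamics import DemeState, Params
from demetech.fixtures import path_fixture, reforming_fixture
from demetech.network import generate_interaction_graph


@pytest.fixture
def rng():
    return random.Random(12345)


@pytest.fixture
def path_deme():
    """4-node path a-i-j-b; i, j play NEW; everyone SI."""
    return path_fixture


@pytest.fixture
def reforming_deme():
    """6-node reforming example: SI pair plays OLD with mixed outside support."""
    return reforming_fixture


@pytest.fixture
def small_deme():
    """A 16-node mixed-type deme on a fresh scale-free graph."""

    def make(alpha=1.5, seed=7, p_si=0.5):
        r = random.Random(seed)
        graph = generate_interaction_graph(16, 4, r)
        types = [1 if r.random() < p_si else 0 for _ in range(16)]
        return DemeState(graph, types, alpha=alpha), r

    return make


def single_deme_steps(alpha, all_si, seed, gens, params_kw=None):
    """Ladder steps of one isolated deme over ``gens`` generations."""
    kw = dict(m=1, n=32, d=6, alpha=alpha, T=2000)
    if params_kw:
        kw.update(params_kw)
    p = Params(**kw)
    r = random.Random(seed)
    types = [1] * p.n if all_si else [0] * p.n
    deme = DemeState(
        generate_interaction_graph(p.n, p.d, r), types,
        alpha=p.schedule.alpha_for(0),
    )
    from demetech.dynamics import run_generation

    total = 0
    for _ in range(gens):
        deme.reset_for_generation(
            generate_interaction_graph(p.n, p.d, r),
            p.schedule.alpha_for(deme.tau),
        )
        total += run_generation(deme, p, r).steps
    return total
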