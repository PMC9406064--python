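from fractions import Fraction
from math import lcm

import numpy as np
import pytest

from pleionet import fixture_networks, generate_ba_network, generate_ncf_rules


@pytest.fixture
def fixtures():
    return fixture_networks()


@pytest.fixture
def neg_loop(fixtures):
    return fixtures["neg_loop_2"]


@pytest.fixture
def const_chain(fixtures):
    return fixtures["const_chain"]


@pytest.fixture
def fig1_star(fixtures):
    return fixtures["fig1_star"]


def random_small_network(seed: int, n_min: int = 3, n_max: int = 10,
                         sign_mode: str = "sign_consistent"):
    """Seeded random Boolean network with n_min..n_max nodes."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_min, n_max + 1))
    m = int(rng.integers(1, min(3, n)))
    graph = generate_ba_network(n, m, seed=int(rng.integers(2**31)),
                                inhibition_prob=0.3)
    net = generate_ncf_rules(graph, seed=int(rng.integers(2**31)),
                             sign_mode=sign_mode)
    return net


def all_states(n: int):
    """All 2**n bit vectors in numeric order."""
    return [
        tuple((i >> (n - 1 - j)) & 1 for j in range(n)) for i in range(1 << n)
    ]


def brute_alignment(wild, mutant) -> Fraction:
    """Alignment distance minimized over ALL lcm offsets (independent oracle)."""
    p, q = len(wild), len(mutant)
    c = lcm(p, q)
    best = min(
        sum(1 for l in range(c) if wild[(l + m) % p] != mutant[l % q])
        for m in range(c)
    )
    return Fraction(best, c)
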