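"""Shared fixtures: parameter profiles, key material, and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from ppgc import mkhe, profiles, rings


def negacyclic_schoolbook(a, b, modulus, n):
    """O(n²) negacyclic convolution oracle: product mod (x^n + 1, modulus)."""
    out = [0] * n
    for i, ai in enumerate(a):
        for j, bj in enumerate(b):
            k = i + j
            if k < n:
                out[k] = (out[k] + int(ai) * int(bj)) % modulus
            else:
                out[k - n] = (out[k - n] - int(ai) * int(bj)) % modulus
    return [x % modulus for x in out]


def small_params(n, n_primes=2, t=None, gadget_base=1 << 8):
    """NTT-valid parameters at a tiny ring dimension for oracle comparisons."""
    primes = profiles.find_ntt_primes(n, n_primes)
    return profiles.make_ring_params(n, primes, t=t, gadget_base=gadget_base,
                                     t_min=1 << 16)


@pytest.fixture(scope="session")
def p16():
    return small_params(16)


@pytest.fixture(scope="session")
def p32():
    return small_params(32)


@pytest.fixture(scope="session")
def tiny_pp():
    return mkhe.setup("tiny", seed=101)


@pytest.fixture(scope="session")
def toy_pp():
    return mkhe.setup("toy", seed=101)


@pytest.fixture(scope="session")
def tiny_keys(tiny_pp):
    """Three key triples at the tiny profile plus their public-material map."""
    rng = np.random.default_rng(7)
    trips = {pid: mkhe.keygen(tiny_pp, pid, rng) for pid in ("alice", "bob", "carol")}
    pubs = {pid: k.public for pid, k in trips.items()}
    return trips, pubs


@pytest.fixture(scope="session")
def toy_keys(toy_pp):
    """Five key triples at the toy profile (for multi-party tests)."""
    rng = np.random.default_rng(11)
    ids = [f"p{i}" for i in range(5)]
    trips = {pid: mkhe.keygen(toy_pp, pid, rng) for pid in ids}
    pubs = {pid: k.public for pid, k in trips.items()}
    return trips, pubs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
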