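"""Named parameter profiles and helpers to construct valid ring parameters.

Profiles
--------
``tiny``
    n = 2^8.  Fast profile for unit tests and quick demos; same plaintext
    modulus policy as ``toy``.
``toy``
    n = 2^10, q a product of seven 30-bit NTT primes (~210 bits).  Correctness
    profile: large enough for exact depth-2 arithmetic with the default
    plaintext modulus plus plaintext multiplications, with generous noise
    margin.  Not a security profile.
``paper``
    n = 2^14, t = 65537, q sized under the 128-bit homomorphic-encryption
    security standard bound for ternary secrets (log q ≲ 438 at this
    dimension).  Heavy; intended for fidelity, not routine testing.

The default plaintext modulus for ``tiny``/``toy`` is the smallest prime
t ≥ 2^33 with t ≡ 1 (mod 2n), which keeps every genomic-test payload exactly
representable under the centered lift (paternity per-locus products reach
~45^4, and fixed-point risk-score payloads reach ~2^31).
"""

from __future__ import annotations

import json
from functools import lru_cache
from pathlib import Path

import sympy

from .rings import ConfigurationError, RingParams

PROFILE_NAMES = ("tiny", "toy", "paper")


def find_ntt_primes(n: int, count: int, below_bits: int = 30) -> tuple:
    """The ``count`` largest primes p < 2^below_bits with p ≡ 1 (mod 2n)."""
    step = 2 * n
    cand = (1 << below_bits) - ((1 << below_bits) - 1) % step
    out = []
    while len(out) < count:
        cand -= step
        if cand <= step:
            raise ConfigurationError(f"not enough NTT primes below 2^{below_bits} for n={n}")
        if sympy.isprime(cand):
            out.append(cand)
    return tuple(out)


def find_plain_modulus(n: int, minimum: int) -> int:
    """Smallest prime t ≥ minimum with t ≡ 1 (mod 2n)."""
    step = 2 * n
    cand = minimum + (1 - minimum) % step
    if cand < minimum:
        cand += step
    while not sympy.isprime(cand):
        cand += step
    return cand


def make_ring_params(
    n: int,
    primes: tuple,
    t: int | None = None,
    sigma_err: float = 3.2,
    gadget_base: int = 1 << 8,
    t_min: int = 1 << 33,
) -> RingParams:
    if t is None:
        t = find_plain_modulus(n, t_min)
    q = 1
    for p in primes:
        q *= int(p)
    return RingParams(
        n=n, q=q, t=int(t), sigma_err=sigma_err, gadget_base=gadget_base, rns_primes=primes
    )


@lru_cache(maxsize=None)
def get_profile(name: str) -> RingParams:
    """Return the ring parameters of a named profile."""
    if name == "tiny":
        return make_ring_params(256, find_ntt_primes(256, 7), gadget_base=1 << 16)
    if name == "toy":
        return make_ring_params(1024, find_ntt_primes(1024, 7), gadget_base=1 << 16)
    if name == "paper":
        return make_ring_params(
            1 << 14, find_ntt_primes(1 << 14, 14), t=65537, gadget_base=1 << 16
        )
    raise KeyError(f"unknown profile {name!r}; available: {PROFILE_NAMES}")


def profile_dict(params: RingParams, crs_seed: int, name: str = "") -> dict:
    return {
        "profile": name,
        "n": params.n,
        "q": params.q,
        "t": params.t,
        "rns_primes": list(params.rns_primes),
        "sigma_err": params.sigma_err,
        "key_dist": params.key_dist,
        "gadget_base": params.gadget_base,
        "crs_seed": crs_seed,
    }


def save_profile(params: RingParams, crs_seed: int, path, name: str = "") -> None:
    Path(path).write_text(json.dumps(profile_dict(params, crs_seed, name), indent=1))


def load_profile(path) -> tuple:
    """Load (RingParams, crs_seed) from a profile file."""
    d = json.loads(Path(path).read_text())
    params = RingParams(
        n=d["n"],
        q=d["q"],
        t=d["t"],
        sigma_err=d["sigma_err"],
        key_dist=d.get("key_dist", "ternary"),
        gadget_base=d["gadget_base"],
        rns_primes=tuple(d["rns_primes"]),
    )
    return params, int(d["crs_seed"])
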