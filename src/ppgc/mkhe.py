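"""Multi-key homomorphic encryption over RLWE with packed ciphertexts.

The scheme is an exact-arithmetic (BFV-style) multi-key construction: each
party independently generates a secret/public/evaluation key triple against a
common reference polynomial vector, single-key ciphertexts are ordinary RLWE
pairs ``(c0, c1)`` with the plaintext carried at scale ``Δ = ⌊q/t⌋``, and
ciphertexts under different keys combine into multi-key ciphertexts
``(c0, c1, …, cN)`` decryptable under the concatenated secret ``(1, s1, …, sN)``.

Multiplication takes the scaled tensor product of two multi-key ciphertexts and
immediately relinearizes it back to ``N+1`` parts using each party's evaluation
key — a gadget "uni-encryption" of its secret against the shared reference
vector — so that noise growth stays linear in the number of parties instead of
exponential.  Decryption is distributed: every party in the ciphertext
contributes a partial decryption share ``c_j·s_j`` masked with smudging noise,
and only the full set of shares recovers the plaintext (N-of-N access control).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import profiles
from .rings import (
    RingElement,
    RingParams,
    SlotVector,
    batch_decode,
    batch_encode,
    gadget_decompose,
    get_tensor_engine,
    sample_error,
    sample_key,
    sample_uniform,
)


class MkheError(Exception):
    """Base class for scheme-level failures."""


class DepthBudgetExceeded(MkheError):
    """A multiplication would exceed the configured multiplicative depth."""


class MissingKeyError(MkheError):
    """A party's public/evaluation key is required but unavailable."""


class ShareError(MkheError):
    """Partial-decryption share set is incomplete, duplicated, or foreign."""


class ScaleMismatch(MkheError):
    """Additive operands carry different fixed-point scales."""


# ---------------------------------------------------------------------------
# Public parameters
# ---------------------------------------------------------------------------

_CRS_CACHE: dict = {}


@dataclass(frozen=True)
class PublicParams:
    """Shared parameters: the ring, the CRS seed, and protocol-wide bounds.

    The common reference polynomials are never transmitted; every party
    regenerates them deterministically from ``crs_seed``.
    """

    ring: RingParams
    crs_seed: int
    smudge_bound: int = 1 << 40
    depth_budget: int = 2
    profile: str = ""

    def crs(self, k: int) -> RingElement:
        """k-th common reference polynomial (uniform in R_q, seed-derived)."""
        key = (self.ring, self.crs_seed, k)
        if key not in _CRS_CACHE:
            h = hashlib.sha256(f"ppgc-crs|{self.crs_seed}|{k}".encode()).digest()
            _CRS_CACHE[key] = sample_uniform(self.ring, int.from_bytes(h[:8], "big"))
        return _CRS_CACHE[key]

    def fingerprint(self) -> str:
        payload = json.dumps(
            {
                "n": self.ring.n,
                "q": self.ring.q,
                "t": self.ring.t,
                "sigma": self.ring.sigma_err,
                "base": self.ring.gadget_base,
                "crs_seed": self.crs_seed,
                "smudge": self.smudge_bound,
                "depth": self.depth_budget,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def setup(profile_name: str, seed: int, **overrides) -> PublicParams:
    """mKH setup: derive public parameters for a named profile.

    Deterministic in ``(profile_name, seed)``; the CRS seed is derived by
    hashing so two different seeds give different reference polynomials.
    """
    ring = profiles.get_profile(profile_name)
    h = hashlib.sha256(f"ppgc-setup|{profile_name}|{seed}".encode()).digest()
    crs_seed = int.from_bytes(h[:8], "big")
    return PublicParams(ring=ring, crs_seed=crs_seed, profile=profile_name, **overrides)


# ---------------------------------------------------------------------------
# Keys
# ---------------------------------------------------------------------------


@dataclass
class PublicKey:
    """A party's public material: encryption key vector and evaluation key.

    ``b[k] = -s·a[k] + e[k]`` over the gadget dimension; index 0 is the
    encryption key.  The evaluation key ``(d0, d1, d2)`` is a uni-encryption of
    the secret: ``d0[k] = -s·d1[k] + e + r·B^k``, ``d2[k] = r·a[k] + e + s·B^k``
    with ``r`` drawn from the key distribution.
    """

    party_id: str
    b: tuple
    d0: tuple
    d1: tuple
    d2: tuple


@dataclass
class KeyTriple:
    """A party's full key material (sk is never serialized by the protocol)."""

    party_id: str
    sk: RingElement
    public: PublicKey

    @property
    def pk(self) -> tuple:
        return self.public.b

    @property
    def ek(self) -> tuple:
        return (self.public.d0, self.public.d1, self.public.d2)


def keygen(
    pp: PublicParams,
    party_id: str,
    rng: np.random.Generator,
    sk_override: RingElement | None = None,
) -> KeyTriple:
    """Generate (sk, pk, ek) for one party from the public parameters.

    ``sk_override`` forces a specific secret (degenerate-path testing only).
    """
    ring = pp.ring
    d = ring.gadget_digits
    s = sk_override if sk_override is not None else sample_key(ring, rng)
    a = [pp.crs(k) for k in range(d)]
    b = tuple(-(s * a[k]) + sample_error(ring, rng) for k in range(d))
    r = sample_key(ring, rng)
    d1 = tuple(sample_uniform(ring, rng) for _ in range(d))
    d0, d2 = [], []
    for k in range(d):
        gk = pow(ring.gadget_base, k, ring.q)
        d0.append(-(s * d1[k]) + sample_error(ring, rng) + r.mul_scalar(gk))
        d2.append(a[k] * r + sample_error(ring, rng) + s.mul_scalar(gk))
    pub = PublicKey(party_id=party_id, b=b, d0=tuple(d0), d1=d1, d2=tuple(d2))
    return KeyTriple(party_id=party_id, sk=s, public=pub)


def _public_of(key) -> PublicKey:
    return key.public if isinstance(key, KeyTriple) else key


# ---------------------------------------------------------------------------
# Ciphertexts
# ---------------------------------------------------------------------------


@dataclass
class Ciphertext:
    """Multi-key ciphertext: parts ``(c0, c1, …, cN)`` for sorted party list."""

    parts: tuple
    parties: tuple
    mult_depth: int = 0
    plain_scale: int = 1

    def __post_init__(self) -> None:
        if len(self.parts) != len(self.parties) + 1:
            raise MkheError("ciphertext must have len(parties)+1 parts")
        if list(self.parties) != sorted(set(self.parties)):
            raise MkheError("party list must be unique and canonically sorted")

    @property
    def params(self) -> RingParams:
        return self.parts[0].params


def _encode_payload(m, ring: RingParams) -> np.ndarray:
    if isinstance(m, SlotVector):
        v = SlotVector.make(m.slots, ring)
    else:
        v = SlotVector.make(np.asarray(m) % ring.t, ring)
    return batch_encode(v, ring)


def _scale_to_q(mu: np.ndarray, ring: RingParams) -> RingElement:
    """Embed a mod-t polynomial at ciphertext scale: round(q·mu/t) per coeff.

    Rounded scaling keeps the per-coefficient embedding error at 1/2 instead
    of the ~(q mod t) error of the plain ⌊q/t⌋·mu embedding, so additive noise
    obeys the triangle inequality.
    """
    scaled = (np.asarray(mu, dtype=object) * ring.q + ring.t // 2) // ring.t
    return RingElement.from_coeffs(ring, scaled)


def encrypt(m, pk, pp: PublicParams, rng: np.random.Generator) -> Ciphertext:
    """Encrypt a slot vector under one party's public key (fresh, depth 0)."""
    pub = _public_of(pk)
    ring = pp.ring
    mu = _encode_payload(m, ring)
    u = sample_key(ring, rng)
    c0 = pub.b[0] * u + sample_error(ring, rng) + _scale_to_q(mu, ring)
    c1 = pp.crs(0) * u + sample_error(ring, rng)
    return Ciphertext(parts=(c0, c1), parties=(pub.party_id,))


def extend(ct: Ciphertext, parties: Iterable[str]) -> Ciphertext:
    """Embed a ciphertext into a larger party set (zero parts for absentees)."""
    target = tuple(sorted(set(parties)))
    if not set(ct.parties) <= set(target):
        raise MkheError("target party set must contain the ciphertext's parties")
    if target == ct.parties:
        return ct
    zero = RingElement.zero(ct.params)
    parts = [ct.parts[0]]
    for pid in target:
        parts.append(ct.parts[ct.parties.index(pid) + 1] if pid in ct.parties else zero)
    return Ciphertext(tuple(parts), target, ct.mult_depth, ct.plain_scale)


def add(ct1: Ciphertext, ct2: Ciphertext) -> Ciphertext:
    """Slot-wise homomorphic addition; operands auto-extend to the union set."""
    if ct1.plain_scale != ct2.plain_scale:
        raise ScaleMismatch(
            f"cannot add payloads at scales {ct1.plain_scale} and {ct2.plain_scale}"
        )
    union = tuple(sorted(set(ct1.parties) | set(ct2.parties)))
    a, b = extend(ct1, union), extend(ct2, union)
    parts = tuple(x + y for x, y in zip(a.parts, b.parts))
    return Ciphertext(parts, union, max(ct1.mult_depth, ct2.mult_depth), ct1.plain_scale)


def negate(ct: Ciphertext) -> Ciphertext:
    return Ciphertext(
        tuple(-p for p in ct.parts), ct.parties, ct.mult_depth, ct.plain_scale
    )


def sub(ct1: Ciphertext, ct2: Ciphertext) -> Ciphertext:
    return add(ct1, negate(ct2))


def _inner_product(digits: Sequence[RingElement], keyvec: Sequence[RingElement]) -> RingElement:
    """sum_k digits[k] * keyvec[k], accumulated in the NTT domain."""
    params = digits[0].params
    from .rings import _get_basis  # local import: private fast path

    basis = _get_basis(params.rns_primes, params.n)
    acc = None
    for dig, key in zip(digits, keyvec):
        term = (dig.ntt() * key.ntt()) % basis.p_col
        acc = term if acc is None else (acc + term) % basis.p_col
    return RingElement(params, basis.inverse(acc).astype(np.int64), acc)


def multiply(
    ct1: Ciphertext,
    ct2: Ciphertext,
    keys: Mapping[str, object],
    pp: PublicParams,
) -> Ciphertext:
    """Homomorphic multiplication: scaled tensor product + relinearization.

    The tensor of two (N+1)-part ciphertexts is rescaled by t/q entry-wise and
    reduced back to a regular (N+1)-part ciphertext using the parties'
    evaluation keys.  Consumes one multiplicative level.
    """
    new_depth = 1 + max(ct1.mult_depth, ct2.mult_depth)
    if new_depth > pp.depth_budget:
        raise DepthBudgetExceeded(
            f"depth {new_depth} exceeds budget {pp.depth_budget}"
        )
    union = tuple(sorted(set(ct1.parties) | set(ct2.parties)))
    for pid in union:
        if pid not in keys:
            raise MissingKeyError(f"no public/evaluation key for party {pid!r}")
    a, b = extend(ct1, union), extend(ct2, union)
    N = len(union)
    ring = pp.ring
    eng = get_tensor_engine(ring)
    X = [None if p.is_zero() else eng.to_ext(p) for p in a.parts]
    Y = [None if p.is_zero() else eng.to_ext(p) for p in b.parts]
    zero = RingElement.zero(ring)

    def tensor(i: int, j: int) -> RingElement:
        if X[i] is None or Y[j] is None:
            return zero
        return eng.scaled_product(X[i], Y[j])

    c0 = tensor(0, 0)
    out = [tensor(0, i) + tensor(i, 0) for i in range(1, N + 1)]
    for i in range(1, N + 1):
        pub_i = _public_of(keys[union[i - 1]])
        for j in range(1, N + 1):
            cij = tensor(i, j)
            if cij.is_zero():
                continue
            pub_j = _public_of(keys[union[j - 1]])
            dec = gadget_decompose(cij, ring)
            cpp = _inner_product(dec, pub_j.b)
            dec2 = gadget_decompose(cpp, ring)
            c0 = c0 + _inner_product(dec2, pub_i.d0)
            out[i - 1] = out[i - 1] + _inner_product(dec2, pub_i.d1)
            out[j - 1] = out[j - 1] + _inner_product(dec, pub_i.d2)
    return Ciphertext(
        (c0, *out), union, new_depth, ct1.plain_scale * ct2.plain_scale
    )


def multiply_plain(ct: Ciphertext, p, scale: int = 1) -> Ciphertext:
    """Slot-wise product with a public plaintext vector; consumes no depth.

    ``scale`` declares the fixed-point scale already baked into ``p`` so the
    ciphertext's carried ``plain_scale`` stays bookkept.
    """
    ring = ct.params
    mu = _encode_payload(p, ring)
    centered = np.where(mu > ring.t // 2, mu - ring.t, mu)
    m_elem = RingElement.from_small(ring, centered.astype(np.int64))
    parts = tuple(part * m_elem for part in ct.parts)
    return Ciphertext(parts, ct.parties, ct.mult_depth, ct.plain_scale * scale)


def add_plain(ct: Ciphertext, p) -> Ciphertext:
    """Slot-wise addition of a public plaintext vector (at the carried scale)."""
    ring = ct.params
    mu = _encode_payload(p, ring)
    parts = (ct.parts[0] + _scale_to_q(mu, ring), *ct.parts[1:])
    return Ciphertext(parts, ct.parties, ct.mult_depth, ct.plain_scale)


# ---------------------------------------------------------------------------
# Distributed decryption
# ---------------------------------------------------------------------------


@dataclass
class PartialDecryption:
    """One party's decryption share: c_j·s_j plus smudging noise."""

    party_id: str
    share: RingElement


def part_dec(
    ct: Ciphertext, key: KeyTriple, pp: PublicParams, rng: np.random.Generator
) -> PartialDecryption:
    """Partially decrypt with one party's secret key.

    The share is masked with noise uniform in [-smudge_bound, smudge_bound] so
    it leaks nothing about the secret key beyond the decryption it enables.
    """
    if key.party_id not in ct.parties:
        raise ShareError(f"party {key.party_id!r} is not part of this ciphertext")
    j = ct.parties.index(key.party_id) + 1
    share = ct.parts[j] * key.sk
    S = pp.smudge_bound
    if S > 0:
        noise = rng.integers(-S, S + 1, pp.ring.n, dtype=np.int64)
        share = share + RingElement.from_small(pp.ring, noise)
    return PartialDecryption(party_id=key.party_id, share=share)


def combine_shares(
    ct: Ciphertext,
    shares: Sequence[PartialDecryption],
    pp: PublicParams,
    check: bool = True,
) -> SlotVector:
    """Merge c0 with decryption shares, rescale by t/q, and decode slots.

    With ``check`` (the protocol path) exactly one share per ciphertext party is
    required.  ``check=False`` combines whatever shares are supplied — used only
    to demonstrate that fewer than N shares decode to garbage.
    """
    ids = [s.party_id for s in shares]
    if check:
        if sorted(ids) != list(ct.parties):
            raise ShareError(
                f"need exactly one share per party {ct.parties}, got {sorted(ids)}"
            )
    ring = pp.ring
    w = ct.parts[0]
    for s in shares:
        w = w + s.share
    c = w.to_coeffs()
    m = ((c * ring.t + ring.q // 2) // ring.q) % ring.t
    return batch_decode(m, ring)


def fin_dec(
    ct: Ciphertext, shares: Sequence[PartialDecryption], pp: PublicParams
) -> SlotVector:
    """Final decryption from the complete set of partial decryptions."""
    return combine_shares(ct, shares, pp, check=True)


def decrypt_with_secrets(
    ct: Ciphertext, sks: Mapping[str, object], pp: PublicParams
) -> SlotVector:
    """Direct decryption given all secret keys (testing convenience)."""
    shares = []
    for pid in ct.parties:
        key = sks[pid]
        sk = key.sk if isinstance(key, KeyTriple) else key
        j = ct.parties.index(pid) + 1
        shares.append(PartialDecryption(pid, ct.parts[j] * sk))
    return combine_shares(ct, shares, pp, check=True)


def noise_of(ct: Ciphertext, sks: Mapping[str, object], pp: PublicParams) -> float:
    """log2 of the max centered residual after exact decryption (white-box).

    Decryption succeeds whenever this is below ``log2(q/(2t))``.
    """
    ring = pp.ring
    w = ct.parts[0]
    for pid in ct.parties:
        key = sks[pid]
        sk = key.sk if isinstance(key, KeyTriple) else key
        w = w + ct.parts[ct.parties.index(pid) + 1] * sk
    c = w.to_coeffs()
    m = ((c * ring.t + ring.q // 2) // ring.q) % ring.t
    residual = (c - (m * ring.q + ring.t // 2) // ring.t) % ring.q
    residual = np.where(residual > ring.q // 2, residual - ring.q, residual)
    mx = max(1, int(np.max(np.abs(residual))))
    return float(np.log2(float(mx)))


def decryption_threshold_bits(pp: PublicParams) -> float:
    """log2(q / (2t)): the noise level beyond which decoding can fail."""
    return float(np.log2(float(pp.ring.q // (2 * pp.ring.t))))
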