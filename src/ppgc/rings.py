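"""Exact arithmetic in the power-of-two cyclotomic ring ``R_q = Z_q[x]/(x^n + 1)``.

This module is the substrate of the whole encryption scheme: ring elements with
coefficients reduced modulo a (possibly multiprecision) modulus ``q``, fast
negacyclic multiplication via number-theoretic transforms, CRT batching of
plaintext slots modulo ``t``, the randomness samplers for keys and errors, and
base-``B`` gadget decomposition used by relinearization.

Internally a ring element is carried in a residue-number-system (RNS)
representation over a fixed set of NTT-friendly word-size primes whose product
is exactly ``q``; the public contract is exact arithmetic mod ``q`` either way,
and canonical ``[0, q)`` coefficients are always recoverable via
:meth:`RingElement.to_coeffs`.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import sympy


class ConfigurationError(ValueError):
    """Raised when ring parameters cannot support the requested operation."""


class ParameterMismatch(ValueError):
    """Raised when two operands belong to different parameter sets."""


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RingParams:
    """Parameters of the ring ``R_q`` and its plaintext space.

    Attributes
    ----------
    n:
        Ring dimension, a power of two; polynomials have degree < n.
    q:
        Ciphertext coefficient modulus, the exact product of ``rns_primes``.
    t:
        Plaintext modulus; a prime with ``t ≡ 1 (mod 2n)`` so that the ring
        ``R_t`` splits into ``n`` independent slots (SIMD batching).
    sigma_err:
        Standard deviation of the discrete-Gaussian error distribution; samples
        beyond ``6*sigma_err`` are rejected, so the tail bound is
        ``floor(6*sigma_err)``.
    key_dist:
        Descriptor of the secret-key distribution; only uniform ternary
        ``{-1, 0, 1}`` is implemented.
    gadget_base:
        Base ``B`` of the digit decomposition used by evaluation keys.
    rns_primes:
        Distinct NTT-friendly primes (each ``≡ 1 mod 2n``) with product ``q``.
    """

    n: int
    q: int
    t: int
    sigma_err: float = 3.2
    key_dist: str = "ternary"
    gadget_base: int = 1 << 8
    rns_primes: tuple = ()

    def __post_init__(self) -> None:
        if self.n < 2 or (self.n & (self.n - 1)) != 0:
            raise ConfigurationError(f"ring dimension n={self.n} must be a power of two")
        if not sympy.isprime(self.t):
            raise ConfigurationError(f"plaintext modulus t={self.t} must be prime")
        if self.t % (2 * self.n) != 1:
            raise ConfigurationError(
                f"t={self.t} must be ≡ 1 (mod 2n={2 * self.n}) for slot batching"
            )
        if not self.t < self.q:
            raise ConfigurationError("require t < q")
        if self.gadget_base < 2:
            raise ConfigurationError("gadget base must be ≥ 2")
        if self.key_dist != "ternary":
            raise ConfigurationError(f"unsupported key distribution {self.key_dist!r}")
        primes = tuple(int(p) for p in self.rns_primes)
        if not primes:
            raise ConfigurationError("rns_primes must be provided (product must equal q)")
        prod = 1
        for p in primes:
            if p % (2 * self.n) != 1:
                raise ConfigurationError(f"RNS prime {p} is not ≡ 1 mod 2n")
            prod *= p
        if prod != self.q:
            raise ConfigurationError("product of rns_primes must equal q")
        if len(set(primes)) != len(primes):
            raise ConfigurationError("rns_primes must be distinct")
        object.__setattr__(self, "rns_primes", primes)

    @property
    def gadget_digits(self) -> int:
        """Number of base-``B`` digits needed to cover ``q`` (⌈log_B q⌉)."""
        d, cap = 0, 1
        while cap < self.q:
            cap *= self.gadget_base
            d += 1
        return d

    @property
    def delta(self) -> int:
        """BFV plaintext scaling factor ``⌊q/t⌋``."""
        return self.q // self.t

    @property
    def error_tail_bound(self) -> int:
        """Hard magnitude bound of error samples (6-sigma rejection cut)."""
        return int(math.floor(6 * self.sigma_err))


# ---------------------------------------------------------------------------
# Negacyclic NTT machinery
# ---------------------------------------------------------------------------


def _bit_reverse_indices(n: int) -> np.ndarray:
    bits = n.bit_length() - 1
    idx = np.arange(n)
    rev = np.zeros(n, dtype=np.int64)
    for b in range(bits):
        rev |= ((idx >> b) & 1) << (bits - 1 - b)
    return rev


class _NttBasis:
    """Batched negacyclic NTT over a tuple of moduli sharing one dimension.

    All moduli must admit a primitive 2n-th root of unity.  When every modulus
    is below 2^31, arithmetic stays in int64 (products < 2^62); otherwise the
    same code path runs on object (big-int) arrays, which is what the plaintext
    modulus t ≥ 2^33 uses.
    """

    def __init__(self, primes: Sequence[int], n: int):
        self.n = n
        self.primes = tuple(int(p) for p in primes)
        for p in self.primes:
            if p % (2 * n) != 1 or not sympy.isprime(p):
                raise ConfigurationError(
                    f"modulus {p} has no primitive 2n-th root of unity (n={n})"
                )
        small = max(self.primes) < (1 << 31)
        self.dtype = np.int64 if small else object
        k = len(self.primes)

        def arr(rows):
            return np.array(rows, dtype=self.dtype)

        psis, ipsis = [], []
        for p in self.primes:
            g = sympy.primitive_root(p)
            psi = pow(int(g), (p - 1) // (2 * n), p)
            assert pow(psi, n, p) == p - 1
            psis.append(psi)
            ipsis.append(pow(psi, -1, p))

        self.p_col = arr([[p] for p in self.primes])  # (k, 1)
        self.psi_pow = arr(
            [[pow(psi, i, p) for i in range(n)] for psi, p in zip(psis, self.primes)]
        )
        ninvs = [pow(n, -1, p) for p in self.primes]
        self.psi_ninv_pow = arr(
            [
                [(pow(ipsi, i, p) * ninv) % p for i in range(n)]
                for ipsi, ninv, p in zip(ipsis, ninvs, self.primes)
            ]
        )
        # Per-stage twiddles for the iterative radix-2 DIT transform.
        self.wf: dict[int, np.ndarray] = {}
        self.wb: dict[int, np.ndarray] = {}
        m = 1
        while m < n:
            rows_f, rows_b = [], []
            for psi, p in zip(psis, self.primes):
                omega = (psi * psi) % p
                wm = pow(omega, n // (2 * m), p)
                iwm = pow(wm, -1, p)
                rows_f.append([pow(wm, j, p) for j in range(m)])
                rows_b.append([pow(iwm, j, p) for j in range(m)])
            self.wf[m] = arr(rows_f)
            self.wb[m] = arr(rows_b)
            m *= 2
        self.brv = _bit_reverse_indices(n)

    def _dit(self, a: np.ndarray, stages: Mapping[int, np.ndarray]) -> np.ndarray:
        k, n = a.shape
        p3 = self.p_col[:, :, None]
        m = 1
        while m < n:
            a = a.reshape(k, n // (2 * m), 2, m)
            u = a[:, :, 0, :]
            v = (a[:, :, 1, :] * stages[m][:, None, :]) % p3
            a = np.concatenate(((u + v) % p3, (u - v) % p3), axis=2)
            a = a.reshape(k, n)
            m *= 2
        return a

    def forward(self, a: np.ndarray) -> np.ndarray:
        """Coefficients -> evaluations at the n roots of x^n + 1 (per modulus)."""
        a = np.asarray(a, dtype=self.dtype)
        a = (a * self.psi_pow) % self.p_col
        return self._dit(a[:, self.brv], self.wf)

    def inverse(self, a: np.ndarray) -> np.ndarray:
        a = np.asarray(a, dtype=self.dtype)
        a = self._dit(a[:, self.brv], self.wb)
        return (a * self.psi_ninv_pow) % self.p_col


@lru_cache(maxsize=64)
def _get_basis(primes: tuple, n: int) -> _NttBasis:
    return _NttBasis(primes, n)


@lru_cache(maxsize=32)
def _crt_weights(primes: tuple) -> tuple:
    """CRT reconstruction weights y_i = (M/p_i) * ((M/p_i)^-1 mod p_i) mod M."""
    M = 1
    for p in primes:
        M *= p
    ws = []
    for p in primes:
        Mi = M // p
        ws.append((Mi * pow(Mi % p, -1, p)) % M)
    return tuple(ws), M


# ---------------------------------------------------------------------------
# Ring elements
# ---------------------------------------------------------------------------


class RingElement:
    """A polynomial of degree < n with coefficients mod q (treated immutable).

    ``rns`` holds the residues mod each prime in coefficient order as an
    int64 array of shape (k, n).  The NTT form is computed lazily and cached.
    """

    __slots__ = ("params", "rns", "_ntt")

    def __init__(self, params: RingParams, rns: np.ndarray, ntt: np.ndarray | None = None):
        self.params = params
        self.rns = rns
        self._ntt = ntt

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_coeffs(cls, params: RingParams, coeffs: Iterable[int]) -> "RingElement":
        """Build from integer coefficients of any sign/size (reduced mod q)."""
        arr = np.array([int(c) for c in coeffs], dtype=object)
        if arr.shape != (params.n,):
            raise ValueError(f"expected {params.n} coefficients, got {arr.shape}")
        rows = [np.asarray(arr % p, dtype=object).astype(np.int64) for p in params.rns_primes]
        return cls(params, np.stack(rows))

    @classmethod
    def from_small(cls, params: RingParams, values: np.ndarray) -> "RingElement":
        """Build from an int64 vector of small (possibly negative) coefficients."""
        v = np.asarray(values, dtype=np.int64)
        if v.shape != (params.n,):
            raise ValueError(f"expected {params.n} coefficients")
        rows = [v % p for p in params.rns_primes]
        return cls(params, np.stack(rows).astype(np.int64))

    @classmethod
    def zero(cls, params: RingParams) -> "RingElement":
        k = len(params.rns_primes)
        return cls(params, np.zeros((k, params.n), dtype=np.int64))

    @classmethod
    def const(cls, params: RingParams, c: int) -> "RingElement":
        v = np.zeros(params.n, dtype=object)
        v[0] = int(c)
        return cls.from_coeffs(params, v)

    # -- conversions --------------------------------------------------------

    def to_coeffs(self) -> np.ndarray:
        """Canonical coefficients in ``[0, q)`` as an object (big-int) array."""
        ws, M = _crt_weights(self.params.rns_primes)
        acc = np.zeros(self.params.n, dtype=object)
        for row, w in zip(self.rns, ws):
            acc = acc + row.astype(object) * w
        return acc % M

    @property
    def coeffs(self) -> tuple:
        return tuple(int(c) for c in self.to_coeffs())

    def centered(self) -> np.ndarray:
        """Signed coefficients via centered lift (x > q/2 maps to x - q)."""
        q = self.params.q
        c = self.to_coeffs()
        return np.where(c > q // 2, c - q, c)

    def ntt(self) -> np.ndarray:
        if self._ntt is None:
            basis = _get_basis(self.params.rns_primes, self.params.n)
            self._ntt = basis.forward(self.rns)
        return self._ntt

    # -- arithmetic ---------------------------------------------------------

    def _check(self, other: "RingElement") -> None:
        if self.params is not other.params and self.params != other.params:
            raise ParameterMismatch("operands use different ring parameters")

    def __add__(self, other: "RingElement") -> "RingElement":
        self._check(other)
        p = np.array(self.params.rns_primes, dtype=np.int64)[:, None]
        ntt = None
        if self._ntt is not None and other._ntt is not None:
            ntt = (self._ntt + other._ntt) % p
        return RingElement(self.params, (self.rns + other.rns) % p, ntt)

    def __sub__(self, other: "RingElement") -> "RingElement":
        self._check(other)
        p = np.array(self.params.rns_primes, dtype=np.int64)[:, None]
        ntt = None
        if self._ntt is not None and other._ntt is not None:
            ntt = (self._ntt - other._ntt) % p
        return RingElement(self.params, (self.rns - other.rns) % p, ntt)

    def __neg__(self) -> "RingElement":
        p = np.array(self.params.rns_primes, dtype=np.int64)[:, None]
        ntt = None if self._ntt is None else (-self._ntt) % p
        return RingElement(self.params, (-self.rns) % p, ntt)

    def __mul__(self, other: "RingElement") -> "RingElement":
        self._check(other)
        basis = _get_basis(self.params.rns_primes, self.params.n)
        prod = (self.ntt() * other.ntt()) % basis.p_col
        return RingElement(self.params, basis.inverse(prod).astype(np.int64), prod)

    def mul_scalar(self, c: int) -> "RingElement":
        rows = []
        for row, p in zip(self.rns, self.params.rns_primes):
            rows.append((row * (int(c) % p)) % p)
        return RingElement(self.params, np.stack(rows))

    def is_zero(self) -> bool:
        return not bool(np.any(self.rns))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RingElement):
            return NotImplemented
        return self.params == other.params and bool(np.array_equal(self.rns, other.rns))

    def __hash__(self):  # pragma: no cover - not used as dict key
        return hash((self.params, self.rns.tobytes()))

    def __repr__(self) -> str:
        return f"RingElement(n={self.params.n}, q~2^{self.params.q.bit_length()})"


# ---------------------------------------------------------------------------
# Spec-level NTT entry points
# ---------------------------------------------------------------------------


def ntt_forward(x: RingElement, params: RingParams) -> np.ndarray:
    """Evaluation-domain representation of ``x`` (shape: primes x n)."""
    if x.params != params:
        raise ParameterMismatch("element does not belong to the given parameters")
    return np.array(x.ntt(), copy=True)


def ntt_inverse(values: np.ndarray, params: RingParams) -> RingElement:
    basis = _get_basis(params.rns_primes, params.n)
    return RingElement(params, basis.inverse(values).astype(np.int64))


def ntt_pointwise(a: np.ndarray, b: np.ndarray, params: RingParams) -> np.ndarray:
    basis = _get_basis(params.rns_primes, params.n)
    return (np.asarray(a) * np.asarray(b)) % basis.p_col


def ring_mul(x: RingElement, y: RingElement, params: RingParams) -> RingElement:
    """Product of ``x`` and ``y`` reduced mod ``(x^n + 1, q)``."""
    if x.params != params or y.params != params:
        raise ParameterMismatch("operands do not conform to params")
    return x * y


def ring_add(x: RingElement, y: RingElement, params: RingParams) -> RingElement:
    if x.params != params or y.params != params:
        raise ParameterMismatch("operands do not conform to params")
    return x + y


# ---------------------------------------------------------------------------
# Samplers
# ---------------------------------------------------------------------------


def sample_uniform(params: RingParams, seed_or_rng) -> RingElement:
    """Uniform element of R_q, reproducible from a public integer seed.

    Accepts either an ``int`` seed (used for the common reference polynomials,
    which every party must be able to regenerate) or a ``numpy.random.Generator``.
    """
    if isinstance(seed_or_rng, (int, np.integer)):
        rnd = random.Random(int(seed_or_rng))
    elif isinstance(seed_or_rng, np.random.Generator):
        rnd = random.Random(int(seed_or_rng.integers(0, 2**63)))
    else:
        raise TypeError("seed_or_rng must be an int seed or numpy Generator")
    coeffs = [rnd.randrange(params.q) for _ in range(params.n)]
    return RingElement.from_coeffs(params, coeffs)


def sample_error(params: RingParams, rng: np.random.Generator) -> RingElement:
    """Discrete Gaussian error: rounded continuous Gaussian, 6-sigma tail cut."""
    if params.sigma_err == 0:
        return RingElement.zero(params)
    bound = params.error_tail_bound
    out = np.rint(rng.normal(0.0, params.sigma_err, params.n)).astype(np.int64)
    bad = np.abs(out) > bound
    while np.any(bad):
        out[bad] = np.rint(rng.normal(0.0, params.sigma_err, int(bad.sum()))).astype(np.int64)
        bad = np.abs(out) > bound
    return RingElement.from_small(params, out)


def sample_key(params: RingParams, rng: np.random.Generator) -> RingElement:
    """Uniform ternary secret with coefficients in {-1, 0, 1}."""
    return RingElement.from_small(params, rng.integers(-1, 2, params.n, dtype=np.int64))


# ---------------------------------------------------------------------------
# Gadget decomposition
# ---------------------------------------------------------------------------


def gadget_decompose(x: RingElement, params: RingParams) -> list:
    """Base-B digits of x: sum_j B^j * part_j == x (mod q), digits in [0, B)."""
    B = params.gadget_base
    d = params.gadget_digits
    c = x.to_coeffs()
    parts = []
    for _ in range(d):
        digit = np.asarray(c % B, dtype=object).astype(np.int64)
        parts.append(RingElement.from_small(params, digit))
        c = c // B
    return parts


def gadget_recompose(parts: Sequence[RingElement], params: RingParams) -> RingElement:
    acc = RingElement.zero(params)
    for j, part in enumerate(parts):
        acc = acc + part.mul_scalar(pow(params.gadget_base, j, params.q))
    return acc


# ---------------------------------------------------------------------------
# Slot batching (plaintext CRT packing)
# ---------------------------------------------------------------------------


@dataclass
class SlotVector:
    """A length-n vector of plaintext slots, entries reduced mod t."""

    slots: np.ndarray

    @classmethod
    def make(cls, values, params: RingParams) -> "SlotVector":
        v = np.asarray(values, dtype=np.int64)
        if v.ndim != 1 or len(v) > params.n:
            raise ValueError(f"slot vector must be 1-D with at most n={params.n} entries")
        if np.any(v < 0) or np.any(v >= params.t):
            raise ValueError("slot values must lie in [0, t)")
        if len(v) < params.n:
            v = np.concatenate([v, np.zeros(params.n - len(v), dtype=np.int64)])
        return cls(v)

    def __len__(self) -> int:
        return len(self.slots)


def batch_encode(v: SlotVector, params: RingParams) -> np.ndarray:
    """Pack slot values into a polynomial mod t (int64 vector of length n).

    Encoding is the inverse negacyclic NTT mod t, so slot-wise addition and
    multiplication commute with ring operations mod (x^n + 1, t).
    """
    basis = _get_basis((params.t,), params.n)
    poly = basis.inverse(np.asarray(v.slots, dtype=basis.dtype).reshape(1, -1))[0]
    return np.asarray(poly, dtype=object).astype(np.int64)


def batch_decode(poly: np.ndarray, params: RingParams) -> SlotVector:
    """Unpack a polynomial mod t back into its slot values."""
    basis = _get_basis((params.t,), params.n)
    slots = basis.forward(np.asarray(poly, dtype=basis.dtype).reshape(1, -1))[0]
    return SlotVector(np.asarray(slots, dtype=object).astype(np.int64))


# ---------------------------------------------------------------------------
# Exact scaled tensor products (for BFV-style multiplication)
# ---------------------------------------------------------------------------


class TensorEngine:
    """Computes round((t/q) * x*y) over the integers, exactly, via an extended
    RNS basis large enough to hold the full negacyclic product of two centered
    operands (|coeff| <= n * (q/2)^2)."""

    def __init__(self, params: RingParams):
        self.params = params
        need = 2 * params.n * params.q * params.q
        primes = list(params.rns_primes)
        prod = math.prod(primes)
        cand = (1 << 30) - ((1 << 30) - 1) % (2 * params.n)  # ≡ 1 mod 2n, ≤ 2^30
        while prod <= need:
            cand -= 2 * params.n
            if cand <= 2 * params.n:
                raise ConfigurationError("ran out of NTT primes for the tensor basis")
            if cand in params.rns_primes:
                continue
            if sympy.isprime(cand):
                primes.append(cand)
                prod *= cand
        self.primes = tuple(primes)
        self.M = prod
        self.basis = _get_basis(self.primes, params.n)
        self.weights, _ = _crt_weights(self.primes)

    def to_ext(self, x: RingElement) -> np.ndarray:
        """NTT of the centered lift of x over the extended basis."""
        c = x.centered()
        rows = [np.asarray(c % p, dtype=object).astype(np.int64) for p in self.primes]
        return self.basis.forward(np.stack(rows))

    def scaled_product(self, X: np.ndarray, Y: np.ndarray) -> RingElement:
        """RingElement with coefficients round(t * (x*y)_i / q) mod q."""
        Z = (X * Y) % self.basis.p_col
        z = self.basis.inverse(Z)
        acc = np.zeros(self.params.n, dtype=object)
        for row, w in zip(z, self.weights):
            acc = acc + row.astype(object) * w
        acc = acc % self.M
        acc = np.where(acc > self.M // 2, acc - self.M, acc)  # centered exact product
        t, q = self.params.t, self.params.q
        scaled = (acc * t + q // 2) // q
        return RingElement.from_coeffs(self.params, scaled)


@lru_cache(maxsize=8)
def get_tensor_engine(params: RingParams) -> TensorEngine:
    return TensorEngine(params)
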