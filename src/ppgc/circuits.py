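"""The four genomic test computations, as plaintext oracles and encrypted circuits.

Each test exists twice:

* a **plaintext oracle** implementing the published scoring formula exactly
  (weighted SNP risk, STR paternity quartic, capped-difference similarity,
  normalized Levenshtein), and
* an **encrypted circuit** over :mod:`ppgc.mkhe` whose decrypted, centered and
  summed slots reproduce the oracle's numerator, so the querier recovers the
  same score after dividing by the public normalizer.

All divisions in the score formulas (1/Σc, 1/K, 1/L, 1/max(m,n)) are public
constants and are applied in plaintext after decryption — exact integer
homomorphic arithmetic cannot divide.  Real-valued parameters (risk weights and
probabilities) are carried in fixed point at a power-of-two scale F.

Score conventions: the personalized-medicine risk is in [0, 1]; paternity is 0
iff the child shares at least one allele with the alleged father at every
locus; the similar-patient score is a mean capped genotype distance; linkage is
a normalized string distance in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np

from . import mkhe
from .rings import SlotVector


class CircuitError(ValueError):
    """Invalid test specification or input domain violation."""


# ---------------------------------------------------------------------------
# Result container
# ---------------------------------------------------------------------------


@dataclass
class ScoredResult:
    """A decrypted test outcome through its post-processing lifecycle.

    ``raw_slots`` are the centered per-slot payloads, ``numerator`` their sum
    over the active slots, ``normalizer`` the public constant divisor of the
    score formula, and ``scale`` the accumulated fixed-point scale; the final
    ``score = numerator / (scale * normalizer)``.
    """

    test: str
    raw_slots: list
    numerator: int
    normalizer: float
    scale: int
    score: float


def centered_slots(slots: SlotVector | np.ndarray, t: int) -> np.ndarray:
    v = np.asarray(slots.slots if isinstance(slots, SlotVector) else slots, dtype=object)
    return np.where(v > t // 2, v - t, v)


def _finalize(test: str, slots, t: int, active: int, normalizer, scale: int) -> ScoredResult:
    raw = centered_slots(slots, t)[:active]
    # The slot sum is only meaningful mod t (zero-sum masking shifts individual
    # slots); re-center the reduced sum, which is exact while |true sum| < t/2.
    numerator = int(np.sum(raw)) % t
    if numerator > t // 2:
        numerator -= t
    return ScoredResult(
        test=test,
        raw_slots=[int(x) for x in raw],
        numerator=numerator,
        normalizer=float(normalizer),
        scale=int(scale),
        score=numerator / (scale * normalizer),
    )


# ---------------------------------------------------------------------------
# Personalized medicine (weighted SNP disease-risk score)
# ---------------------------------------------------------------------------


@dataclass
class PMSpec:
    """Parameters of the SNP risk score: per-SNP weights and risk-allele
    probabilities, plus the fixed-point scale F used under encryption."""

    n_snps: int
    weights: Sequence[float]
    probs: Sequence[float]
    scale_F: int = 1 << 10

    def __post_init__(self) -> None:
        if len(self.weights) != self.n_snps or len(self.probs) != self.n_snps:
            raise CircuitError("weights and probs must have length n_snps")
        if any(w < 0 for w in self.weights):
            raise CircuitError("weights must be non-negative")
        if any(not (0 < p < 1) for p in self.probs):
            raise CircuitError("probabilities must lie strictly inside (0, 1)")
        if self.scale_F < 2 or (self.scale_F & (self.scale_F - 1)) != 0:
            raise CircuitError("scale_F must be a power of two")


def pm_presence_bits(genotypes) -> np.ndarray:
    """Map {0,1,2} genotypes to minor-allele presence bits {0,1}.

    The risk factor pr^s (1-pr)^(1-s) is only defined for s in {0,1}; a
    genotype counts as carrying the risk allele iff at least one copy is
    present.
    """
    g = np.asarray(genotypes, dtype=np.int64)
    if np.any((g < 0) | (g > 2)):
        raise CircuitError("genotypes must be coded in {0,1,2}")
    return (g >= 1).astype(np.int64)


def pm_risk_plain(genotype_bits, spec: PMSpec) -> float:
    """Weighted mean of pr_j^{s_j} (1-pr_j)^{1-s_j} over the relevant SNPs."""
    s = np.asarray(genotype_bits, dtype=np.int64)
    if len(s) != spec.n_snps:
        raise CircuitError("genotype vector length must equal n_snps")
    if np.any((s < 0) | (s > 1)):
        raise CircuitError("PM test consumes presence bits in {0,1}")
    f = [p if si == 1 else 1 - p for si, p in zip(s, spec.probs)]
    wsum = float(np.sum(spec.weights))
    return float(np.dot(spec.weights, f) / wsum)


def pm_risk_circuit(enc_bits: mkhe.Ciphertext, spec: PMSpec, pp: mkhe.PublicParams) -> mkhe.Ciphertext:
    """Depth-0 encrypted risk score via the exact linearization
    f(s) = (1-pr) + s·(2pr-1); per-slot payload ≈ F²·c_j·f_j."""
    t = pp.ring.t
    F = spec.scale_F
    B = [round(F * (2 * p - 1)) % t for p in spec.probs]  # slope, signed mod t
    A = [round(F * (1 - p)) for p in spec.probs]  # intercept at scale F
    C = [round(F * w) for w in spec.weights]
    ct = mkhe.multiply_plain(enc_bits, np.array(B, dtype=np.int64) % t, scale=F)
    ct = mkhe.add_plain(ct, np.array(A, dtype=np.int64))
    ct = mkhe.multiply_plain(ct, np.array(C, dtype=np.int64), scale=F)
    return ct


def pm_finalize(slots, spec: PMSpec, pp: mkhe.PublicParams) -> ScoredResult:
    wsum = float(np.sum(spec.weights))
    return _finalize("pm", slots, pp.ring.t, spec.n_snps, wsum, spec.scale_F**2)


def pm_quantization_bound(spec: PMSpec) -> float:
    """Score error bound of the fixed-point circuit: 2/F."""
    return 2.0 / spec.scale_F


# ---------------------------------------------------------------------------
# Paternity testing (STR quartic match statistic)
# ---------------------------------------------------------------------------


@dataclass
class PaternitySpec:
    """K STR loci compared between a child and an alleged father."""

    K: int = 13
    locus_names: tuple = ()

    def __post_init__(self) -> None:
        if self.K < 1:
            raise CircuitError("K must be ≥ 1")
        if not self.locus_names:
            self.locus_names = tuple(f"locus_{i + 1:02d}" for i in range(self.K))
        if len(self.locus_names) != self.K:
            raise CircuitError("locus_names must have length K")


def _locus_pairs(profile: Mapping, spec: PaternitySpec):
    alleles = getattr(profile, "alleles", profile)
    try:
        return [(int(alleles[name][0]), int(alleles[name][1])) for name in spec.locus_names]
    except KeyError as exc:
        raise CircuitError(f"profile is missing locus {exc.args[0]!r}") from exc


def paternity_locus_stat(x1: int, x2: int, y1: int, y2: int) -> int:
    """(x1-y1)(x1-y2)(x2-y1)(x2-y2): zero iff a child allele matches one of
    the father's."""
    return (x1 - y1) * (x1 - y2) * (x2 - y1) * (x2 - y2)


def paternity_plain(child: Mapping, father: Mapping, spec: PaternitySpec) -> Fraction:
    """Mean per-locus quartic statistic, exact as a rational number."""
    c = _locus_pairs(child, spec)
    f = _locus_pairs(father, spec)
    total = sum(paternity_locus_stat(x1, x2, y1, y2) for (x1, x2), (y1, y2) in zip(c, f))
    return Fraction(total, spec.K)


def paternity_circuit(
    enc_child: tuple,
    enc_father: tuple,
    spec: PaternitySpec,
    pp: mkhe.PublicParams,
    keys: Mapping[str, object],
) -> mkhe.Ciphertext:
    """Encrypted per-locus quartic: 4 subtractions, 3 multiplications, depth 2.

    ``enc_child`` / ``enc_father`` are the two allele lanes of each profile
    (locus i in slot i), each lane encrypted under its owner's key.
    """
    c1, c2 = enc_child
    f1, f2 = enc_father
    d11 = mkhe.sub(c1, f1)
    d12 = mkhe.sub(c1, f2)
    d21 = mkhe.sub(c2, f1)
    d22 = mkhe.sub(c2, f2)
    m1 = mkhe.multiply(d11, d12, keys, pp)
    m2 = mkhe.multiply(d21, d22, keys, pp)
    return mkhe.multiply(m1, m2, keys, pp)


def paternity_payload_bound_ok(max_allele_delta: int, pp: mkhe.PublicParams) -> bool:
    """Per-slot exactness condition for the centered lift: t > 2·max|Δ|⁴."""
    return pp.ring.t > 2 * max_allele_delta**4


def paternity_finalize(slots, spec: PaternitySpec, pp: mkhe.PublicParams) -> ScoredResult:
    return _finalize("paternity", slots, pp.ring.t, spec.K, spec.K, 1)


# ---------------------------------------------------------------------------
# Similar patient search (capped genotype distance)
# ---------------------------------------------------------------------------


@dataclass
class SPSSpec:
    """Profile length L and the cap c of the per-site difference min(|a-b|, c)."""

    L: int
    cap_c: int = 2

    def __post_init__(self) -> None:
        if self.L < 1:
            raise CircuitError("L must be ≥ 1")
        if self.cap_c < 0:
            raise CircuitError("cap must be a non-negative integer")


def _check_genotypes(v) -> np.ndarray:
    g = np.asarray(v, dtype=np.int64)
    if np.any((g < 0) | (g > 2)):
        raise CircuitError("genotypes must be coded in {0,1,2}")
    return g


def sps_plain(a_profile, b_profile, spec: SPSSpec) -> float:
    """(1/L)·Σ min(|a_i - b_i|, c) over the genotype vectors."""
    a = _check_genotypes(a_profile)
    b = _check_genotypes(b_profile)
    if len(a) != spec.L or len(b) != spec.L:
        raise CircuitError("profile length mismatch with spec.L")
    return float(np.mean(np.minimum(np.abs(a - b), spec.cap_c)))


def abs_interp_coeffs(domain_radius: int, t: int) -> list:
    """Coefficients over Z_t of the unique even polynomial with p(d) = |d| on
    the integers d in [-r, r].

    The polynomial has degree 2r and only even powers; the returned list is
    indexed by power of d (length 2r+1).  For r=2 this is 6⁻¹·(7d² - d⁴).
    """
    r = domain_radius
    if r < 1:
        raise CircuitError("domain radius must be ≥ 1")
    # Interpolate q(u) with u = d² over nodes u_k = k², values k (Lagrange).
    nodes = [k * k for k in range(r + 1)]
    qcoef = [0] * (r + 1)  # coefficients of q in u
    for k in range(r + 1):
        # Lagrange basis ell_k(u) = prod_{j≠k} (u - u_j) / (u_k - u_j)
        denom = 1
        for j in range(r + 1):
            if j != k:
                denom *= nodes[k] - nodes[j]
        try:
            denom_inv = pow(denom % t, -1, t)
        except ValueError as exc:
            raise CircuitError(f"interpolation denominator not invertible mod {t}") from exc
        basis = [1]  # polynomial coefficients in u, ascending
        for j in range(r + 1):
            if j == k:
                continue
            new = [0] * (len(basis) + 1)
            for i, bc in enumerate(basis):
                new[i] = (new[i] - bc * nodes[j]) % t
                new[i + 1] = (new[i + 1] + bc) % t
            basis = new
        for i, bc in enumerate(basis):
            qcoef[i] = (qcoef[i] + k * bc % t * denom_inv) % t
    out = [0] * (2 * r + 1)
    for i, c in enumerate(qcoef):
        out[2 * i] = c % t
    return out


def min_cap_numerators(cap: int, scale: int = 12) -> tuple:
    """Small-integer numerators (α, β) with min(|d|, cap) = (α·d² + β·d⁴)/scale
    for all d in [-2, 2] (the genotype-difference domain).

    Keeping the plaintext multipliers small avoids the ~32-bit noise cost of
    multiplying by modular inverses mod t; the division by ``scale`` is exact
    and happens after decryption.
    """
    v1 = min(1, cap)
    v2 = min(2, cap)
    beta = v2 - 4 * v1  # 12·b where p(u)=a·u+b·u², u=d²
    alpha = 16 * v1 - v2  # 12·a
    for d in (-2, -1, 0, 1, 2):
        assert (alpha * d * d + beta * d**4) % scale == 0
        assert (alpha * d * d + beta * d**4) // scale == min(abs(d), cap)
    return alpha, beta


def sps_circuit(
    enc_a: mkhe.Ciphertext,
    enc_b: mkhe.Ciphertext,
    spec: SPSSpec,
    pp: mkhe.PublicParams,
    keys: Mapping[str, object],
) -> mkhe.Ciphertext:
    """Encrypted capped distance via even-polynomial interpolation of
    min(|d|, c) on d in [-2, 2]; two ciphertext squarings (depth 2) plus a
    small-integer plaintext combination.  Payload is 12·min(|d|,c) per slot."""
    t = pp.ring.t
    alpha, beta = min_cap_numerators(spec.cap_c)
    d = mkhe.sub(enc_a, enc_b)
    d2 = mkhe.multiply(d, d, keys, pp)
    d4 = mkhe.multiply(d2, d2, keys, pp)
    term2 = mkhe.multiply_plain(d2, np.full(spec.L, alpha % t, dtype=np.int64))
    term4 = mkhe.multiply_plain(d4, np.full(spec.L, beta % t, dtype=np.int64))
    return mkhe.add(term2, term4)


def sps_finalize(slots, spec: SPSSpec, pp: mkhe.PublicParams) -> ScoredResult:
    res = _finalize("sps", slots, pp.ring.t, spec.L, spec.L, 12)
    return res


# ---------------------------------------------------------------------------
# Record linkage (edit distance; encrypted variant: Hamming on one-hot)
# ---------------------------------------------------------------------------


@dataclass
class LinkageSpec:
    """Record-comparison layout: symbol alphabet, fixed padded record length.

    The padding character must be part of the alphabet so that every symbol
    mismatch (including against padding) flips exactly two one-hot bits.
    """

    field_alphabet: str = "abcdefghijklmnopqrstuvwxyz #"
    record_len: int = 16
    pad_char: str = "#"

    def __post_init__(self) -> None:
        if not self.field_alphabet:
            raise CircuitError("alphabet must be non-empty")
        if len(set(self.field_alphabet)) != len(self.field_alphabet):
            raise CircuitError("alphabet symbols must be unique")
        if self.pad_char not in self.field_alphabet:
            raise CircuitError("pad_char must be part of the alphabet")

    @property
    def bits_per_record(self) -> int:
        return self.record_len * len(self.field_alphabet)


def levenshtein(a: str, b: str) -> int:
    """Textbook dynamic-programming edit distance (the reference semantic)."""
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
        prev = cur
    return prev[n]


def linkage_plain_levenshtein(rec_a: str, rec_b: str, spec: LinkageSpec) -> float:
    """Edit distance normalized by max(m, n); 0 for identical records."""
    if max(len(rec_a), len(rec_b)) == 0:
        return 0.0
    return levenshtein(rec_a, rec_b) / max(len(rec_a), len(rec_b))


def one_hot_record(record: str, spec: LinkageSpec) -> np.ndarray:
    """One-hot bits of a record padded to ``record_len`` symbols."""
    if len(record) > spec.record_len:
        raise CircuitError(f"record longer than padded length {spec.record_len}")
    padded = record + spec.pad_char * (spec.record_len - len(record))
    A = len(spec.field_alphabet)
    bits = np.zeros(spec.record_len * A, dtype=np.int64)
    for i, ch in enumerate(padded):
        try:
            bits[i * A + spec.field_alphabet.index(ch)] = 1
        except ValueError as exc:
            raise CircuitError(f"symbol {ch!r} not in alphabet") from exc
    return bits


def linkage_hamming_plain(rec_a: str, rec_b: str, spec: LinkageSpec) -> float:
    """Normalized symbol Hamming distance of padded records (the semantics the
    encrypted circuit computes)."""
    pa = rec_a + spec.pad_char * (spec.record_len - len(rec_a))
    pb = rec_b + spec.pad_char * (spec.record_len - len(rec_b))
    return sum(x != y for x, y in zip(pa, pb)) / spec.record_len


def linkage_circuit(
    enc_a: mkhe.Ciphertext,
    enc_b: mkhe.Ciphertext,
    spec: LinkageSpec,
    pp: mkhe.PublicParams,
    keys: Mapping[str, object],
) -> mkhe.Ciphertext:
    """Per-slot payload (a_bit - b_bit)² over one-hot records; depth 1.

    Each mismatching symbol position flips exactly two bits, so the slot sum
    divided by 2·record_len is the normalized Hamming distance.
    """
    if enc_a.params.n < spec.bits_per_record:
        raise CircuitError("one-hot record does not fit into the slot count")
    d = mkhe.sub(enc_a, enc_b)
    return mkhe.multiply(d, d, keys, pp)


def linkage_finalize(slots, spec: LinkageSpec, pp: mkhe.PublicParams) -> ScoredResult:
    return _finalize(
        "linkage", slots, pp.ring.t, spec.bits_per_record, 2 * spec.record_len, 1
    )


# ---------------------------------------------------------------------------
# Aggregate-only release masking
# ---------------------------------------------------------------------------


def mask_zero_sum(
    ct: mkhe.Ciphertext,
    active_slots: Sequence[int],
    pp: mkhe.PublicParams,
    rng: np.random.Generator,
) -> mkhe.Ciphertext:
    """Add a plaintext mask that hides per-slot values but preserves the sum
    over ``active_slots`` (the mask is zero-sum there, uniform elsewhere).

    With a single active slot the mask is forced to zero at that slot so the
    released value is exactly the aggregate.
    """
    t = pp.ring.t
    n = pp.ring.n
    active = sorted(set(int(i) for i in active_slots))
    if any(i < 0 or i >= n for i in active):
        raise CircuitError("active slot index out of range")
    r = rng.integers(0, t, n, dtype=np.int64)
    if len(active) == 1:
        r[active[0]] = 0
    elif active:
        head = active[:-1]
        r[active[-1]] = (-int(np.sum(r[head].astype(object)))) % t
    return mkhe.add_plain(ct, r)
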