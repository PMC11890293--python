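# Methods

## Setting

`ppgc` implements a privacy-preserving framework for small- and medium-scale
genomic computations. Individuals' genomic profiles — SNP genotype vectors
coded {0,1,2}, STR profiles of 13–20 loci with two integer repeat counts per
locus, and string records for database linkage — are encrypted once, each
under its owner's own key, and stored at a cloud storage-and-processing unit
(SPU). The SPU evaluates genomic test circuits directly on ciphertexts,
including circuits that combine data encrypted under *different* parties'
keys, and the result can only be opened when every involved party contributes
a partial decryption (N-of-N access control). Four roles participate: a key
authority publishing parameters, a certified institution that sequences and
encrypts, the SPU, and the data owners/queriers.

## The multi-key scheme

The cryptosystem is an exact-arithmetic (BFV-style) multi-key homomorphic
encryption scheme over the RLWE ring `R_q = Z_q[x]/(x^n + 1)`, n a power of
two.

**Keys.** All parties share a seed-derived common reference vector
`a ∈ R_q^d` (d = gadget digits). Party i samples a uniform ternary secret
`s_i` and publishes `b_i = -s_i·a + e_i` plus an evaluation key — a gadget
"uni-encryption" of `s_i`:

    d1 uniform,  d0 = -s_i·d1 + e + r_i·g,  d2 = r_i·a + e + s_i·g,

with `g = (B^0, …, B^{d-1})` the gadget vector and `r_i` ternary.

**Encryption.** A plaintext slot vector is CRT-packed into a polynomial
mod t (t prime, t ≡ 1 mod 2n, so `R_t` splits into n slots and one
homomorphic operation acts slot-wise on all of them), embedded at ciphertext
scale by `round(q·m/t)` per coefficient, and encrypted as an ordinary RLWE
pair `(c0, c1)` against `(b_i[0], a[0])`. The rounded embedding (rather than
`⌊q/t⌋·m`) keeps the embedding error at 1/2 per coefficient so that additive
noise obeys the triangle inequality.

**Multi-key operations.** Ciphertexts under different keys extend to a common
sorted party list with zero parts; addition is component-wise. Multiplication
takes the exact scaled tensor `round(t/q · c_i·c_j)` of the two `(N+1)`-part
ciphertexts, then relinearizes every `s_i·s_j` component back onto
`(1, s_1, …, s_N)` with a two-step gadget product against `b_j` and party i's
evaluation key. This keeps post-multiplication noise growth linear in the
number of parties rather than exponential, which the suite verifies
empirically (fixed product embedded in party sets N = 2…5).

**Distributed decryption.** Party j's share is `c_j·s_j + e_smudge` with
smudging noise uniform in `[-2^40, 2^40]` (noise flooding; the bound is far
inside the correctness margin and far above the scheme noise). Merging `c0`
with all N shares, rescaling by `t/q` and rounding recovers the plaintext
polynomial; any N−1 shares leave a uniformly wrong phase, which the suite
checks on 100 withheld-share trials.

## Parameter profiles

| profile | n | log2 q | t | gadget base | role |
|---|---|---|---|---|---|
| tiny | 2^8 | ~210 (7×30-bit primes) | smallest prime ≥ 2^33, ≡1 mod 2n | 2^16 | unit tests, demos |
| toy | 2^10 | ~210 (7×30-bit primes) | same policy | 2^16 | default; acceptance runs |
| paper | 2^14 | ~418 (14×30-bit primes) | 65537 | 2^16 | fidelity with the 128-bit HE-standard sizing |

Numerical choices, and why:

* **q as a product of NTT primes.** Exact mod-q arithmetic is carried in an
  RNS over word-size primes ≡ 1 (mod 2n), so every ring product is a batched
  negacyclic NTT in int64; canonical `[0,q)` coefficients are recovered by CRT
  on demand. The scaled tensor product is computed *exactly* over an extended
  RNS basis large enough to hold `n·(q/2)^2`, then rounded — no floating
  point anywhere in the ciphertext path.
* **t ≥ 2^33 by default.** The paternity statistic is a per-locus quartic;
  with repeat counts in [5, 50] a slot payload reaches 45^4 ≈ 4.1·10^6 and
  the centered lift needs `t > 2·|payload|` with a wide margin for sums and
  fixed-point risk payloads (≈ F^2·max weight ≈ 2^22). A ~2^33 prime makes
  every circuit payload exactly representable. The `paper` profile keeps the
  classical 65537 plaintext modulus for fidelity; it is sufficient for the
  SNP-scale tests but not for exact 13-locus quartic payloads.
* **q sized for depth 2 plus plaintext products.** One BFV multiplication
  multiplies noise by roughly `2n·t` (~2^44 at toy). From ~2^8 fresh noise,
  depth 2 lands near 2^115; the decryption threshold is `q/(2t)` ≈ 2^176, so
  there is ~60 bits of headroom for plaintext multiplications and additions
  after the quartic. This is why toy q has seven primes, not five.
* **Gadget base 2^16 in the profiles** (type default 2^8): halves the digit
  count d, and hence relinearization cost, while the added relinearization
  noise (~d·n·B·6σ ≈ 2^35) is negligible against the threshold.
* **Error distribution:** rounded Gaussian, σ = 3.2, rejection beyond 6σ
  (standard HE practice); key and encryption randomness uniform ternary.
* **Security status.** `tiny`/`toy` are correctness profiles: at their
  dimensions the RLWE instance is *not* secure and they must never protect
  real data. `paper` follows the homomorphic-encryption security standard's
  128-bit table for ternary secrets at n = 2^14 (log q ≤ 438; we use ~418).

## The four test circuits

All score divisions (1/Σc, 1/K, 1/L, 1/max(m,n)) are public constants applied
in plaintext after decryption; integer HE cannot divide. Signed payloads use
the centered lift mod t.

* **Personalized medicine** (SNP risk score). The published factor
  `pr^s·(1-pr)^{1-s}` is undefined at genotype 2, so the circuit consumes a
  minor-allele *presence bit* s ∈ {0,1} and evaluates the exact degree-1
  linearization `f(s) = (1-pr) + s·(2pr-1)` — identical values on {0,1} —
  with weights and probabilities quantized as `round(F·x)`, F = 2^10. The
  whole circuit is plaintext multiplications and additions: zero ciphertext-
  ciphertext depth. Decrypted score error is bounded by 2/F; the suite checks
  this on 100 random spec/genotype draws (weights in [1,4], so the
  quantization error of the weighted mean stays within the stated bound).
* **Paternity** (STR). Per locus, `(x1-y1)(x1-y2)(x2-y1)(x2-y2)` vanishes
  iff the child shares an allele with the alleged father. Four allele lanes
  (two per party, each under its owner's key), 4 homomorphic subtractions and
  3 multiplications arranged as `(d11·d12)·(d21·d22)`: depth exactly 2. The
  score is the slot sum over K loci divided by K, exact.
* **Similar patient search.** `min(|a-b|, c)` on the genotype-difference
  domain d ∈ [-2, 2] is an even function, hence a polynomial in d²; the
  circuit squares the difference twice (depth 2) and combines with the
  *integer numerators* of the interpolation — `(α·d² + β·d⁴)/12` with α, β
  small integers — dividing by 12 after decryption. Multiplying by small
  integers instead of modular inverses mod t avoids ~32 bits of extra noise
  per plaintext product. `abs_interp_coeffs` provides the general even
  interpolant (e.g. `6^{-1}(7d² - d⁴)` for |d| on radius 2) for any prime t
  with invertible denominators.
* **Record linkage.** The reference semantic is the normalized Levenshtein
  distance, implemented as the textbook DP oracle (cross-checked against the
  edlib aligner in the suite). A full homomorphic Levenshtein DP is
  incompatible with a depth-2 budget, so the *encrypted* circuit computes the
  normalized Hamming distance over one-hot-encoded records padded to a fixed
  length: one subtraction and one squaring (depth 1); each symbol mismatch
  flips exactly two bits, so the slot sum divided by `2·record_len` is the
  symbol mismatch rate. This deviation is deliberate and visible in the API
  (`linkage_plain_levenshtein` vs `linkage_hamming_plain`/`linkage_circuit`).

**Aggregate-only release.** The scheme has no rotation keys, so per-slot
results are summed by the querier after decryption. To avoid leaking
per-locus values, the SPU adds a zero-sum mask before release: uniform slots
whose sum over the active range is 0 mod t (and uniform junk elsewhere).
Consequently score numerators are reconstructed as the centered value of the
slot sum mod t, which is exact while the true numerator is below t/2 — a
bound every circuit's payload satisfies by construction.

## Protocol model

Roles run in one process and exchange the same serialized bytes the CLI
writes to disk (length-prefixed containers with a JSON header and a parameter
fingerprint; the CRS travels only as a seed). A transcript recorder captures
every inter-role message; the suite scans all demo transcripts for the raw
and packed encodings of every secret key and for the plaintext genotype/
allele/record bytes, and requires zero hits. Beyond the trust model of the
framework itself, the artifact adds a minimal per-profile consent list
(owner-granted querier ids) as practical plumbing; it is an authorization
convenience, not a cryptographic boundary. Withdrawal deletes a party's
keys, profiles, and any evaluated results that involve them; a second
withdrawal warns and is a no-op.

## Synthetic data: what it does and does not model

Generators exist to exercise the cryptographic pipeline, not to be
population-genetically realistic: SNP genotypes are independent
binomial(2, MAF) draws (no linkage disequilibrium, no population structure);
STR alleles are uniform integer repeat counts in [5, 50] over 13 generic
loci; a Mendelian child inherits one uniformly chosen allele per locus from
each parent, which guarantees a zero paternity score for true trios;
"unrelated" pairs for classification checks are drawn from disjoint allele
ranges ([5,20] vs [30,50]) so no locus factor can vanish. Record tables are
random lowercase fields with i.i.d. substitution typos. Passing tests
therefore certify the cryptographic and arithmetic behavior of the framework
on such inputs — not forensic or clinical validity of the scores on real
panels (no STR mutation model, no calibrated likelihood ratios, no real
allele-frequency spectra).

## Problem sizes used by the suite

The default verification runs use the toy profile (n = 2^10): 200 random
depth-≤2 circuits over 1–5 parties; 100 random inputs per test type,
evaluated slot-parallel (e.g. 78 thirteen-locus trios per ciphertext batch);
50 Mendelian trios and 50 disjoint-range pairs for classification; 100
multiply-relinearize noise measurements and 100 withheld-share trials. These
sizes exploit the scheme's batching — a single homomorphic operation acts on
all n slots — which is also why the framework's cost is flat in the input
size until a batch fills up.

## Known limitations

* No rotation/Galois keys (slot aggregation happens after decryption, under
  zero-sum masking), no bootstrapping, N-of-N decryption only.
* Arithmetic is reference-grade Python/numpy: exact and auditable, not
  constant-time, and far from optimized RNS implementations in C++.
* The encrypted linkage circuit is Hamming-on-one-hot, not edit distance.
* Inference attacks from repeated query results are out of scope, as is any
  formal security proof; the suite only checks behavioral smoke properties
  (randomized encryptions, share hygiene, transcript confinement).
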