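# ppgc — privacy-preserving genomic computations

`ppgc` is a reference implementation of a cloud-outsourced framework for
running genomic tests on **encrypted** data with **multi-key homomorphic
encryption**: every data owner encrypts their genome once under their *own*
key, a storage-and-processing unit (SPU) evaluates test circuits directly on
the ciphertexts — including circuits combining profiles encrypted under
different parties' keys — and a result can only be opened when *all*
involved parties contribute a partial decryption. It is aimed at
individual-level and small-database analyses (paternity tests, SNP risk
scores, similar-patient search, cross-database record linkage), not at
GWAS-scale statistics.

## What it computes

The cryptosystem is an exact BFV-style multi-key scheme over the RLWE ring
`R_q = Z_q[x]/(x^n + 1)` with CRT slot packing mod a prime `t ≡ 1 (mod 2n)`,
gadget-based relinearization against a shared reference vector, and
distributed (N-of-N) decryption with smudging noise. On top of it sit four
test circuits with exact plaintext oracles:

| test | score | encrypted circuit depth |
|---|---|---|
| personalized medicine | `S = (Σ_j c_j · pr_j^{s_j}(1-pr_j)^{1-s_j}) / Σ_j c_j` | 0 (linearized, fixed point F=2^10) |
| paternity (K STR loci) | `S = (1/K) Σ_i (x_{i1}-y_{i1})(x_{i1}-y_{i2})(x_{i2}-y_{i1})(x_{i2}-y_{i2})` | 2 (4 subs, 3 mults) |
| similar patient search | `S = (1/L) Σ_i min(|a_i - b_i|, c)` | 2 (even-polynomial interpolation of min∘abs) |
| record linkage | `S = lev(a, b) / max(m, n)` (plain oracle); encrypted circuit: normalized Hamming over one-hot records | 1 |

A zero paternity score means the child shares at least one allele with the
alleged father at every locus — guaranteed for Mendelian children, and
impossible for profiles drawn from disjoint allele ranges.

## Worked example

```python
import numpy as np
from ppgc import circuits, mkhe, synthetic

pp = mkhe.setup("toy", seed=7)                       # public parameters
rng = np.random.default_rng(7)
keys = {pid: mkhe.keygen(pp, pid, rng) for pid in ("child", "father")}
pubs = {pid: k.public for pid, k in keys.items()}

spec = circuits.PaternitySpec(K=13)
mother, father = synthetic.gen_str_population(2, K=13, rng=rng)
child = synthetic.gen_child(mother, father, rng, child_id="child")

def encrypt_lanes(profile, pid):                     # two allele lanes per profile
    a1, a2 = profile.lanes()
    return (mkhe.encrypt(a1, keys[pid].public, pp, rng),
            mkhe.encrypt(a2, keys[pid].public, pp, rng))

ct = circuits.paternity_circuit(encrypt_lanes(child, "child"),
                                encrypt_lanes(father, "father"), spec, pp, pubs)
print("multiplicative depth:", ct.mult_depth)
print("encrypted under:", ct.parties)

shares = [mkhe.part_dec(ct, keys[pid], pp, rng) for pid in ct.parties]
res = circuits.paternity_finalize(mkhe.fin_dec(ct, shares, pp), spec, pp)
print("paternity score:", res.score)
print("plaintext oracle:", float(circuits.paternity_plain(child, father, spec)))
```

prints

```
multiplicative depth: 2
encrypted under: ('child', 'father')
paternity score: 0.0
plaintext oracle: 0.0
```

The child and father profiles never meet in plaintext: each is encrypted
under its owner's key, the product circuit runs on the two-key ciphertext,
and both parties must contribute a share before the score exists anywhere.
A score of 0.0 is a paternity match; an unrelated pair from a disjoint
allele range scores ≈ 2·10^5 on the same panel.

## Command line

```sh
ppgc gen --kind trio --out fixtures --seed 5       # synthetic Mendelian trio
ppgc setup --profile toy --seed 1 --out pp.json    # key authority
ppgc keygen --party CHILD0000 --params pp.json --out-dir keys
ppgc encrypt --params pp.json --pub keys/CHILD0000.ppgc.pub \
     --profile-kind str --in fixtures/CHILD0000.str.csv --out child
ppgc query --test paternity --params pp.json --spec-file spec.json \
     --in child.lane0.ppgc.ct --in child.lane1.ppgc.ct \
     --in father.lane0.ppgc.ct --in father.lane1.ppgc.ct \
     --pub keys/CHILD0000.ppgc.pub --pub keys/FATHER.ppgc.pub --out eval.ct
ppgc partdec ... ; ppgc findec ...                 # distributed decryption
ppgc demo --scenario paternity --profile toy --seed 7   # full scripted run
```

Exit codes: 0 success, 2 validation error, 3 crypto-correctness failure,
4 access-control refusal. A `demo` run reports every decrypted score next to
its plaintext oracle and audits the full message transcript for plaintext or
secret-key leakage; see `docs/methods.md` for the model, the parameter
profiles, and the design decisions.

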