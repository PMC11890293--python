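"""End-to-end scripted scenarios: one per genomic test type.

Each scenario generates synthetic inputs, runs all four protocol phases
(setup/keygen, sequencing/encryption, encrypted test, distributed decryption),
cross-checks every decrypted score against the plaintext oracle, and audits
the message transcript for plaintext or secret-key leakage.  Used by the CLI
``demo`` command and by the test suite.
"""

from __future__ import annotations

import numpy as np

from . import circuits, mkhe, protocol, synthetic

SCENARIOS = ("pm", "paternity", "sps", "linkage")


class CryptoCorrectnessError(Exception):
    """Decrypted score disagrees with the plaintext oracle."""


def _result_entry(label: str, score: float, oracle: float, tol: float) -> dict:
    ok = abs(score - oracle) <= tol
    return {
        "label": label,
        "score": score,
        "oracle": oracle,
        "tolerance": tol,
        "ok": bool(ok),
    }


def run_scenario(
    name: str,
    seed: int = 0,
    profile: str = "toy",
    mask: bool = True,
    related: bool = True,
    n_db: int = 20,
) -> dict:
    """Run one scripted scenario end to end and return a result report.

    Raises :class:`CryptoCorrectnessError` if any decrypted score disagrees
    with its oracle beyond the test's tolerance.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    rng = np.random.default_rng([seed, 0xD0])
    runner = {
        "pm": _scenario_pm,
        "paternity": _scenario_paternity,
        "sps": _scenario_sps,
        "linkage": _scenario_linkage,
    }[name]
    dep, results, needles = runner(seed, profile, mask, rng, related=related, n_db=n_db)
    needles.update(dep.secret_needles())
    hits = dep.transcript.scan(needles)
    report = {
        "scenario": name,
        "profile": profile,
        "seed": seed,
        "masking": mask,
        "results": results,
        "transcript_messages": len(dep.transcript.messages),
        "transcript_leaks": [f"message {i}: {label}" for i, label in hits],
        "all_ok": all(r["ok"] for r in results) and not hits,
    }
    bad = [r for r in results if not r["ok"]]
    if bad:
        raise CryptoCorrectnessError(
            f"{len(bad)} decrypted score(s) disagree with the oracle: {bad[:3]}"
        )
    return report


# ---------------------------------------------------------------------------


def _scenario_pm(seed, profile, mask, rng, **_) -> tuple:
    n_snps = 30
    dep = protocol.Deployment.setup(["patient"], profile=profile, seed=seed)
    prof = synthetic.gen_snp_profiles(1, n_snps, 0.25, rng, id_prefix="PM")[0]
    spec = circuits.PMSpec(
        n_snps=n_snps,
        weights=[float(w) for w in rng.uniform(1.0, 4.0, n_snps)],
        probs=[float(p) for p in rng.uniform(0.1, 0.9, n_snps)],
    )
    bits = circuits.pm_presence_bits(prof.genotypes)
    bit_prof = synthetic.SNPProfile(
        prof.individual_id, prof.variant_ids, prof.chromosomes, prof.positions, bits
    )
    dep.sequence_and_encrypt("patient", bit_prof, "snp")
    query = protocol.TestQuery(
        test="pm", querier="patient", targets=[("patient", "default")],
        spec=spec, test_id="pm-demo", mask=mask,
    )
    dep.run_encrypted_test(query)
    outputs = dep.run_decryption("pm-demo")
    oracle = circuits.pm_risk_plain(bits, spec)
    tol = circuits.pm_quantization_bound(spec)
    results = [
        _result_entry(label, res.score, oracle, tol) for label, res in outputs
    ]
    needles = {
        "plaintext-genotypes": bytes(prof.genotypes.astype(np.uint8)),
        "plaintext-bits": bytes(bits.astype(np.uint8)),
    }
    return dep, results, needles


def _scenario_paternity(seed, profile, mask, rng, related=True, **_) -> tuple:
    dep = protocol.Deployment.setup(["child", "father"], profile=profile, seed=seed)
    spec = circuits.PaternitySpec(K=13)
    if related:
        mother, father = synthetic.gen_str_population(2, K=13, rng=rng)
        child = synthetic.gen_child(mother, father, rng, child_id="child")
    else:
        # Disjoint allele ranges guarantee no shared allele at any locus.
        child = synthetic.gen_str_population(1, K=13, allele_range=(5, 20), rng=rng)[0]
        father = synthetic.gen_str_population(1, K=13, allele_range=(30, 50), rng=rng)[0]
        child.allele_range = synthetic.DEFAULT_ALLELE_RANGE
        father.allele_range = synthetic.DEFAULT_ALLELE_RANGE
    dep.sequence_and_encrypt("child", child, "str", consent={"father", "child"})
    dep.sequence_and_encrypt("father", father, "str", consent={"father", "child"})
    query = protocol.TestQuery(
        test="paternity", querier="child",
        targets=[("child", "default"), ("father", "default")],
        spec=spec, test_id="pt-demo", mask=mask,
    )
    dep.run_encrypted_test(query)
    outputs = dep.run_decryption("pt-demo")
    oracle = float(circuits.paternity_plain(child, father, spec))
    results = [_result_entry(label, res.score, oracle, 0.0) for label, res in outputs]
    lanes = np.concatenate([np.concatenate(child.lanes()), np.concatenate(father.lanes())])
    needles = {"plaintext-alleles": bytes(lanes.astype(np.uint8))}
    return dep, results, needles


def _scenario_sps(seed, profile, mask, rng, n_db=20, **_) -> tuple:
    L = 40
    dep = protocol.Deployment.setup(["querier", "clinic"], profile=profile, seed=seed)
    spec = circuits.SPSSpec(L=L, cap_c=2)
    qprof = synthetic.gen_snp_profiles(1, L, 0.3, rng, id_prefix="Q")[0]
    db = synthetic.gen_snp_profiles(n_db, L, 0.3, rng, id_prefix="DB")
    dep.sequence_and_encrypt("querier", qprof, "snp", consent={"querier", "clinic"})
    targets = [("querier", "default")]
    for i, prof in enumerate(db):
        pid = f"patient{i:03d}"
        dep.sequence_and_encrypt("clinic", prof, "snp", profile_id=pid,
                                 consent={"querier", "clinic"})
        targets.append(("clinic", pid))
    query = protocol.TestQuery(
        test="sps", querier="querier", targets=targets,
        spec=spec, test_id="sps-demo", mask=mask,
    )
    dep.run_encrypted_test(query)
    outputs = dep.run_decryption("sps-demo")
    results = []
    for (label, res), prof in zip(outputs, db):
        oracle = circuits.sps_plain(qprof.genotypes, prof.genotypes, spec)
        results.append(_result_entry(label, res.score, oracle, 0.0))
    needles = {"plaintext-query-genotypes": bytes(qprof.genotypes.astype(np.uint8))}
    for i, prof in enumerate(db[:3]):
        needles[f"plaintext-db-genotypes-{i}"] = bytes(prof.genotypes.astype(np.uint8))
    return dep, results, needles


def _scenario_linkage(seed, profile, mask, rng, **_) -> tuple:
    dep = protocol.Deployment.setup(["registryA", "registryB"], profile=profile, seed=seed)
    alphabet = circuits.LinkageSpec().field_alphabet
    record_len = min(16, dep.pp.ring.n // len(alphabet))  # one-hot bits must fit the slots
    spec = circuits.LinkageSpec(record_len=record_len)
    field_len = (record_len - 1) // 2
    table_a, table_b, labels = synthetic.gen_record_pairs(
        6, typo_rate=0.15, rng=rng, field_len=field_len
    )
    targets = []
    for i in range(len(table_a.rows)):
        rec_a = table_a.joined(i)
        rec_b = table_b.joined(i)
        dep.sequence_and_encrypt("registryA", (spec, rec_a), "record",
                                 profile_id=f"rec{i}", consent={"registryA", "registryB"})
        dep.sequence_and_encrypt("registryB", (spec, rec_b), "record",
                                 profile_id=f"rec{i}", consent={"registryA", "registryB"})
        targets += [("registryA", f"rec{i}"), ("registryB", f"rec{i}")]
    query = protocol.TestQuery(
        test="linkage", querier="registryA", targets=targets,
        spec=spec, test_id="rl-demo", mask=mask,
    )
    dep.run_encrypted_test(query)
    outputs = dep.run_decryption("rl-demo")
    results = []
    for (label, res), i in zip(outputs, range(len(table_a.rows))):
        rec_a, rec_b = table_a.joined(i), table_b.joined(i)
        oracle = circuits.linkage_hamming_plain(rec_a, rec_b, spec)
        entry = _result_entry(label, res.score, oracle, 0.0)
        entry["levenshtein_oracle"] = circuits.linkage_plain_levenshtein(rec_a, rec_b, spec)
        entry["is_match"] = labels[i]
        results.append(entry)
    needles = {
        f"plaintext-record-{i}": table_a.joined(i).encode()
        for i in range(len(table_a.rows))
    }
    return dep, results, needles
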