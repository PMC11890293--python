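"""Four-role protocol: key authority, certified institution, storage unit, parties.

The orchestration mirrors the deployment the scheme is designed for: a key
authority (KA) publishes public parameters; each data owner generates its own
key triple and registers the public material; a certified institution (CI)
"sequences" biological samples (mocked as parsing/validating a genomic profile
file or object) and encrypts each profile under its owner's public key; a
storage and processing unit (SPU) stores only ciphertexts and public keys,
evaluates the requested test circuit under the union of the participants'
keys, and relays partial-decryption shares; only the querier can combine all
shares into the plaintext score (N-of-N access control).

All roles communicate through an in-process message bus carrying the same
serialized bytes the CLI writes to disk, so a transcript recorder can assert
that no inter-role message ever contains plaintext genotypes or secret keys.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import circuits, mkhe, serialize, synthetic
from .rings import SlotVector

logger = logging.getLogger("ppgc.protocol")


def _stable_hash(s: str) -> int:
    """Process-independent 31-bit hash (str.hash is randomized per run)."""
    return int.from_bytes(hashlib.sha256(s.encode()).digest()[:4], "big") & 0x7FFFFFFF


class ProtocolError(Exception):
    pass


class UnknownParty(ProtocolError):
    pass


class MissingProfile(ProtocolError):
    pass


class AccessDenied(ProtocolError):
    """Querier is not on the consent list of a referenced profile."""


class IncompleteDecryption(ProtocolError):
    """A required partial-decryption share was not contributed."""


# ---------------------------------------------------------------------------
# Transport: in-process bus with a transcript recorder
# ---------------------------------------------------------------------------


@dataclass
class Message:
    sender: str
    receiver: str
    kind: str
    payload: bytes


class Transcript:
    """Recorder over every inter-role message, for confinement auditing."""

    def __init__(self) -> None:
        self.messages: list = []

    def record(self, sender: str, receiver: str, kind: str, payload: bytes) -> None:
        self.messages.append(Message(sender, receiver, kind, payload))

    def scan(self, needles: Mapping[str, bytes]) -> list:
        """Return (message index, needle label) for every needle found in any
        message payload; an empty list means the transcript is clean."""
        hits = []
        for i, msg in enumerate(self.messages):
            for label, needle in needles.items():
                if needle and needle in msg.payload:
                    hits.append((i, label))
        return hits


# ---------------------------------------------------------------------------
# Roles
# ---------------------------------------------------------------------------


@dataclass
class Party:
    """A data owner / querier H_i.  The secret key never leaves this object."""

    party_id: str
    keys: mkhe.KeyTriple
    rng: np.random.Generator
    results: dict = field(default_factory=dict)


@dataclass
class StoredProfile:
    kind: str  # "snp" | "str" | "record"
    owner: str
    profile_id: str
    cts: tuple  # one ct (snp/record) or two allele lanes (str)
    meta: dict
    consent: set


@dataclass
class EvaluatedTest:
    query: "TestQuery"
    result_cts: list  # list of (label, Ciphertext)
    shares: dict = field(default_factory=dict)  # label -> {party_id: share}


@dataclass
class TestQuery:
    """A request for one of the four tests.

    ``targets`` are (owner, profile_id) pairs; their meaning per test:
    pm: the single profile scored; paternity: (child, father); sps: the
    querier's profile first, then each database profile to compare against;
    linkage: pairs of record profiles from the two databases.
    """

    test: str
    querier: str
    targets: list
    spec: object
    test_id: str
    mask: bool = True

    __test__ = False  # not a test case, despite the name
    _VALID = ("pm", "paternity", "sps", "linkage")

    def __post_init__(self) -> None:
        if self.test not in self._VALID:
            raise ProtocolError(f"unknown test {self.test!r}")


class SPU:
    """Cloud storage and processing unit: ciphertexts and public keys only."""

    def __init__(self, pp: mkhe.PublicParams, transcript: Transcript):
        self.pp = pp
        self.transcript = transcript
        self.public_keys: dict = {}
        self.profiles: dict = {}
        self.tests: dict = {}

    def register_public_key(self, sender: str, payload: bytes) -> None:
        self.transcript.record(sender, "SPU", "public_key", payload)
        pub = serialize.public_key_from_bytes(payload, self.pp)
        self.public_keys[pub.party_id] = pub

    def store_profile(self, sender: str, owner: str, profile_id: str, kind: str,
                      ct_payloads: Sequence[bytes], meta: dict, consent: set) -> None:
        if owner not in self.public_keys:
            raise UnknownParty(f"party {owner!r} has no registered keys")
        for blob in ct_payloads:
            self.transcript.record(sender, "SPU", f"encrypted_profile/{kind}", blob)
        cts = tuple(serialize.ciphertext_from_bytes(b, self.pp) for b in ct_payloads)
        self.profiles[(owner, profile_id)] = StoredProfile(
            kind=kind, owner=owner, profile_id=profile_id, cts=cts,
            meta=dict(meta), consent=set(consent),
        )

    def fetch_profile(self, owner: str, profile_id: str, kind: str, querier: str) -> StoredProfile:
        try:
            prof = self.profiles[(owner, profile_id)]
        except KeyError:
            raise MissingProfile(f"no stored profile {(owner, profile_id)}")
        if prof.kind != kind:
            raise ProtocolError(
                f"profile {(owner, profile_id)} has kind {prof.kind!r}, test needs {kind!r}"
            )
        if querier not in prof.consent and querier != owner:
            raise AccessDenied(f"{querier!r} lacks consent for profile of {owner!r}")
        return prof

    def withdraw(self, party_id: str) -> None:
        """GDPR-style deletion: drop the party's keys, profiles, and results."""
        known = party_id in self.public_keys or any(
            owner == party_id for owner, _ in self.profiles
        )
        if not known:
            warnings.warn(f"withdraw: party {party_id!r} not present (no-op)")
            return
        self.public_keys.pop(party_id, None)
        for key in [k for k in self.profiles if k[0] == party_id]:
            del self.profiles[key]
        for tid in [t for t, ev in self.tests.items()
                    if party_id in ev.query.participants or party_id == ev.query.querier]:
            del self.tests[tid]
        logger.info("SPU: withdrew party %s", party_id)


# ---------------------------------------------------------------------------
# Deployment: wiring + the four protocol phases
# ---------------------------------------------------------------------------


def _participants(query: TestQuery) -> tuple:
    owners = {owner for owner, _ in query.targets}
    owners.add(query.querier)
    return tuple(sorted(owners))


TestQuery.participants = property(lambda self: _participants(self))


class Deployment:
    """An in-process instantiation of all four roles."""

    def __init__(self, pp: mkhe.PublicParams, seed: int):
        self.pp = pp
        self.transcript = Transcript()
        self.spu = SPU(pp, self.transcript)
        self.parties: dict = {}
        self._seed = seed
        self._rng = np.random.default_rng([seed, 0xC1])

    # -- Phase 1: setup and key generation ---------------------------------

    @classmethod
    def setup(cls, party_ids: Sequence[str], profile: str = "toy", seed: int = 0,
              **pp_overrides) -> "Deployment":
        """KA generates public parameters; each party generates and registers
        its keys.  Deterministic given the seed."""
        if len(set(party_ids)) != len(party_ids):
            raise ProtocolError("duplicate party id")
        pp = mkhe.setup(profile, seed, **pp_overrides)
        dep = cls(pp, seed)
        dep.transcript.record("KA", "*", "public_params", serialize.params_to_json(pp).encode())
        for pid in party_ids:
            dep.add_party(pid)
        return dep

    def add_party(self, party_id: str) -> Party:
        """Key generation for one party; also supports dynamic late join."""
        if party_id in self.parties:
            raise ProtocolError(f"duplicate party id {party_id!r}")
        rng = np.random.default_rng([self._seed, _stable_hash(party_id), 0x5E])
        keys = mkhe.keygen(self.pp, party_id, rng)
        party = Party(party_id=party_id, keys=keys, rng=rng)
        self.parties[party_id] = party
        self.spu.register_public_key(
            party_id, serialize.public_key_to_bytes(keys.public, self.pp)
        )
        return party

    # -- Phase 2: sequencing and encryption --------------------------------

    def sequence_and_encrypt(self, party_id: str, raw_profile, kind: str,
                             profile_id: str = "default", consent=()) -> None:
        """CI mock-sequences (validates) a profile and encrypts it under the
        owner's public key; only ciphertexts reach the SPU."""
        if party_id not in self.parties:
            raise UnknownParty(f"party {party_id!r} not registered")
        party = self.parties[party_id]
        ci_rng = np.random.default_rng(
            [self._seed, _stable_hash(f"{party_id}/{profile_id}"), 0xC1]
        )
        pub = party.keys.public
        if kind == "snp":
            prof = self._seq_snp(raw_profile)
            ct = mkhe.encrypt(prof.genotypes % self.pp.ring.t, pub, self.pp, ci_rng)
            payloads = [serialize.ciphertext_to_bytes(ct, self.pp)]
            meta = {"n_snps": len(prof), "variant_ids": list(prof.variant_ids)}
        elif kind == "str":
            prof = self._seq_str(raw_profile)
            lanes = prof.lanes()
            cts = [mkhe.encrypt(lane, pub, self.pp, ci_rng) for lane in lanes]
            payloads = [serialize.ciphertext_to_bytes(c, self.pp) for c in cts]
            meta = {"loci": list(prof.loci)}
        elif kind == "record":
            spec, record = raw_profile
            bits = circuits.one_hot_record(record, spec)
            ct = mkhe.encrypt(bits, pub, self.pp, ci_rng)
            payloads = [serialize.ciphertext_to_bytes(ct, self.pp)]
            meta = {"record_len": spec.record_len, "alphabet": spec.field_alphabet}
        else:
            raise ProtocolError(f"unknown profile kind {kind!r}")
        self.spu.store_profile(
            "CI", party_id, profile_id, kind, payloads, meta,
            consent=set(consent) | {party_id},
        )

    @staticmethod
    def _seq_snp(raw) -> synthetic.SNPProfile:
        if isinstance(raw, synthetic.SNPProfile):
            return raw
        return synthetic.read_snp_tsv(raw)

    @staticmethod
    def _seq_str(raw) -> synthetic.STRProfile:
        if isinstance(raw, synthetic.STRProfile):
            return raw
        return synthetic.read_str_csv(raw)

    # -- Phase 3: encrypted genomic test -----------------------------------

    def run_encrypted_test(self, query: TestQuery) -> str:
        """SPU selects the relevant encrypted profiles and evaluates the test;
        the result is encrypted under all participants' keys."""
        spu = self.spu
        keys = spu.public_keys
        for target in query.targets:
            if tuple(target) not in spu.profiles:
                raise MissingProfile(f"no stored profile {tuple(target)}")
        for pid in query.participants:
            if pid not in keys:
                raise UnknownParty(f"participant {pid!r} has no registered keys")
        results = []
        mask_rng = np.random.default_rng([self._seed, _stable_hash(query.test_id), 0xA5])
        if query.test == "pm":
            (owner, prof_id) = query.targets[0]
            prof = spu.fetch_profile(owner, prof_id, "snp", query.querier)
            bits_ct = prof.cts[0]
            ct = circuits.pm_risk_circuit(bits_ct, query.spec, self.pp)
            active = range(query.spec.n_snps)
            results.append((f"{owner}/{prof_id}", self._mask(ct, active, query, mask_rng)))
        elif query.test == "paternity":
            (child, child_pid), (father, father_pid) = query.targets
            cprof = spu.fetch_profile(child, child_pid, "str", query.querier)
            fprof = spu.fetch_profile(father, father_pid, "str", query.querier)
            if cprof.meta["loci"] != fprof.meta["loci"]:
                raise ProtocolError("paternity test requires identical locus panels")
            ct = circuits.paternity_circuit(cprof.cts, fprof.cts, query.spec, self.pp, keys)
            results.append(("paternity", self._mask(ct, range(query.spec.K), query, mask_rng)))
        elif query.test == "sps":
            (qowner, qpid), *others = query.targets
            qprof = spu.fetch_profile(qowner, qpid, "snp", query.querier)
            for owner, pid in others:
                prof = spu.fetch_profile(owner, pid, "snp", query.querier)
                ct = circuits.sps_circuit(qprof.cts[0], prof.cts[0], query.spec, self.pp, keys)
                results.append((f"{owner}/{pid}", self._mask(ct, range(query.spec.L), query, mask_rng)))
        elif query.test == "linkage":
            if len(query.targets) % 2 != 0:
                raise ProtocolError("linkage targets must come in pairs")
            spec = query.spec
            for (oa, pa), (ob, pb) in zip(query.targets[::2], query.targets[1::2]):
                prof_a = spu.fetch_profile(oa, pa, "record", query.querier)
                prof_b = spu.fetch_profile(ob, pb, "record", query.querier)
                ct = circuits.linkage_circuit(prof_a.cts[0], prof_b.cts[0], spec, self.pp, keys)
                results.append((f"{oa}/{pa}|{ob}/{pb}",
                                self._mask(ct, range(spec.bits_per_record), query, mask_rng)))
        spu.tests[query.test_id] = EvaluatedTest(query=query, result_cts=results)
        for label, ct in results:
            self.transcript.record(
                "SPU", query.querier, f"evaluated/{query.test}",
                serialize.ciphertext_to_bytes(ct, self.pp),
            )
        return query.test_id

    def _mask(self, ct, active, query: TestQuery, rng) -> mkhe.Ciphertext:
        if not query.mask:
            return ct
        return circuits.mask_zero_sum(ct, list(active), self.pp, rng)

    # -- Phase 4: distributed decryption -----------------------------------

    def run_decryption(self, test_id: str):
        """Every participant except the querier sends its share via the SPU;
        the querier adds its own share and recovers the score(s)."""
        ev = self.spu.tests.get(test_id)
        if ev is None:
            raise MissingProfile(f"no evaluated test {test_id!r}")
        query = ev.query
        querier = self.parties[query.querier]
        outputs = []
        for label, ct in ev.result_cts:
            shares = []
            for pid in ct.parties:
                if pid == query.querier:
                    continue
                if pid not in self.parties:
                    raise IncompleteDecryption(f"participant {pid!r} unreachable")
                party = self.parties[pid]
                share = mkhe.part_dec(ct, party.keys, self.pp, party.rng)
                blob = serialize.share_to_bytes(share, self.pp)
                self.transcript.record(pid, "SPU", "partial_decryption", blob)
                self.transcript.record("SPU", query.querier, "partial_decryption", blob)
                shares.append(share)
            if query.querier in ct.parties:
                shares.append(mkhe.part_dec(ct, querier.keys, self.pp, querier.rng))
            slots = mkhe.fin_dec(ct, shares, self.pp)
            outputs.append((label, self._finalize(query, slots)))
        querier.results[test_id] = outputs
        return outputs

    def _finalize(self, query: TestQuery, slots: SlotVector) -> circuits.ScoredResult:
        if query.test == "pm":
            return circuits.pm_finalize(slots, query.spec, self.pp)
        if query.test == "paternity":
            return circuits.paternity_finalize(slots, query.spec, self.pp)
        if query.test == "sps":
            return circuits.sps_finalize(slots, query.spec, self.pp)
        return circuits.linkage_finalize(slots, query.spec, self.pp)

    # -- withdrawal ---------------------------------------------------------

    def withdraw(self, party_id: str) -> None:
        self.spu.withdraw(party_id)
        self.parties.pop(party_id, None)

    # -- auditing helpers ---------------------------------------------------

    def secret_needles(self) -> dict:
        """Byte patterns of every secret key (for transcript scanning).

        Two encodings per key: the ternary coefficients as raw bytes, and the
        packed big-endian form the serializer would emit if a secret key were
        ever (wrongly) placed in a message.
        """
        out = {}
        for pid, party in self.parties.items():
            centered = party.keys.sk.centered().astype(object) + 1
            out[f"sk-raw:{pid}"] = bytes(int(c) % 256 for c in centered)
            packed = serialize.secret_key_to_bytes(party.keys, self.pp)
            out[f"sk-packed:{pid}"] = packed[packed.find(b"}") + 1 :]
        return out
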