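"""Multi-key scheme: keygen, encryption, evaluation, distributed decryption."""

import dataclasses

import numpy as np
import pytest

from ppgc import mkhe, serialize
from ppgc.rings import RingElement, get_tensor_engine


def enc(pp, trips, pid, values, rng):
    return mkhe.encrypt(values, trips[pid].public, pp, rng)


class TestSetup:
    def test_deterministic_given_seed(self):
        a = mkhe.setup("tiny", seed=5)
        b = mkhe.setup("tiny", seed=5)
        assert a.fingerprint() == b.fingerprint()
        assert serialize.params_to_json(a) == serialize.params_to_json(b)
        assert a.crs(0) == b.crs(0)

    def test_different_seeds_give_different_crs(self):
        a = mkhe.setup("tiny", seed=5)
        b = mkhe.setup("tiny", seed=6)
        assert a.crs(0) != b.crs(0)

    def test_profile_satisfies_ring_invariants(self, toy_pp):
        ring = toy_pp.ring
        assert ring.n == 1024 and ring.t % (2 * ring.n) == 1 and ring.t < ring.q
        assert ring.gadget_base ** ring.gadget_digits >= ring.q

    def test_unknown_profile_rejected(self):
        with pytest.raises(KeyError):
            mkhe.setup("nonexistent", seed=0)


class TestKeygen:
    def test_pk_residual_is_bounded_error(self, tiny_pp, tiny_keys):
        """b + s·a must equal the sampled error: small under the tail bound."""
        trips, _ = tiny_keys
        key = trips["alice"]
        for k in range(tiny_pp.ring.gadget_digits):
            resid = key.public.b[k] + key.sk * tiny_pp.crs(k)
            assert int(np.max(np.abs(resid.centered().astype(object)))) <= \
                tiny_pp.ring.error_tail_bound

    def test_parties_share_the_reference_polynomial(self, tiny_pp):
        """Both parties' keys are built against the identical CRS from setup."""
        assert tiny_pp.crs(0) == mkhe.setup("tiny", seed=101).crs(0)

    def test_zero_secret_zero_error_gives_zero_pk(self, tiny_pp):
        ring0 = dataclasses.replace(tiny_pp.ring, sigma_err=0.0)
        pp0 = dataclasses.replace(tiny_pp, ring=ring0)
        zero = RingElement.zero(ring0)
        key = mkhe.keygen(pp0, "z", np.random.default_rng(0), sk_override=zero)
        assert all(b.is_zero() for b in key.public.b)


class TestEncryptDecrypt:
    def test_round_trip(self, tiny_pp, tiny_keys, rng):
        trips, _ = tiny_keys
        m = rng.integers(0, tiny_pp.ring.t, tiny_pp.ring.n)
        ct = enc(tiny_pp, trips, "alice", m, rng)
        assert ct.mult_depth == 0 and len(ct.parts) == 2
        got = mkhe.decrypt_with_secrets(ct, {"alice": trips["alice"]}, tiny_pp)
        assert np.array_equal(got.slots, m)

    def test_encryptions_are_randomized(self, tiny_pp, tiny_keys, rng):
        trips, _ = tiny_keys
        m = np.arange(tiny_pp.ring.n) % 100
        c1 = enc(tiny_pp, trips, "alice", m, rng)
        c2 = enc(tiny_pp, trips, "alice", m, rng)
        assert c1.parts[0] != c2.parts[0]

    def test_add_zero_is_identity(self, tiny_pp, tiny_keys, rng):
        trips, _ = tiny_keys
        m = rng.integers(0, 500, tiny_pp.ring.n)
        ct = mkhe.add(
            enc(tiny_pp, trips, "alice", m, rng),
            enc(tiny_pp, trips, "alice", np.zeros(tiny_pp.ring.n, dtype=int), rng),
        )
        got = mkhe.decrypt_with_secrets(ct, {"alice": trips["alice"]}, tiny_pp)
        assert np.array_equal(got.slots, m)

    def test_out_of_range_slot_rejected(self, tiny_pp, tiny_keys, rng):
        trips, _ = tiny_keys
        from ppgc.rings import SlotVector

        with pytest.raises(ValueError):
            bad = SlotVector(np.full(tiny_pp.ring.n, tiny_pp.ring.t, dtype=np.int64))
            mkhe.encrypt(bad, trips["alice"].public, tiny_pp, rng)


class TestExtend:
    def test_same_set_is_identity(self, tiny_pp, tiny_keys, rng):
        trips, _ = tiny_keys
        ct = enc(tiny_pp, trips, "alice", np.ones(8, dtype=int), rng)
        assert mkhe.extend(ct, ("alice",)) is ct

    def test_extension_preserves_plaintext(self, tiny_pp, tiny_keys, rng):
        trips, _ = tiny_keys
        m = rng.integers(0, 100, tiny_pp.ring.n)
        ct = mkhe.extend(enc(tiny_pp, trips, "alice", m, rng), ("alice", "bob", "carol"))
        assert len(ct.parts) == 4
        got = mkhe.decrypt_with_secrets(ct, trips, tiny_pp)
        assert np.array_equal(got.slots, m)

    def test_non_superset_rejected(self, tiny_pp, tiny_keys, rng):
        trips, _ = tiny_keys
        ct = enc(tiny_pp, trips, "alice", np.ones(8, dtype=int), rng)
        with pytest.raises(mkhe.MkheError):
            mkhe.extend(ct, ("bob", "carol"))

    def test_two_key_addition_end_to_end(self, tiny_pp, tiny_keys, rng):
        trips, _ = tiny_keys
        t = tiny_pp.ring.t
        m1 = rng.integers(0, t, tiny_pp.ring.n)
        m2 = rng.integers(0, t, tiny_pp.ring.n)
        ct = mkhe.add(
            enc(tiny_pp, trips, "alice", m1, rng), enc(tiny_pp, trips, "bob", m2, rng)
        )
        got = mkhe.decrypt_with_secrets(ct, trips, tiny_pp)
        assert np.array_equal(got.slots, (m1 + m2) % t)

    def test_modular_wraparound(self, tiny_pp, tiny_keys, rng):
        trips, _ = tiny_keys
        t, n = tiny_pp.ring.t, tiny_pp.ring.n
        ct = mkhe.add(
            enc(tiny_pp, trips, "alice", np.full(n, t - 1, dtype=np.int64), rng),
            enc(tiny_pp, trips, "alice", np.ones(n, dtype=np.int64), rng),
        )
        got = mkhe.decrypt_with_secrets(ct, {"alice": trips["alice"]}, tiny_pp)
        assert not np.any(got.slots)

    def test_scale_mismatch_rejected(self, tiny_pp, tiny_keys, rng):
        trips, _ = tiny_keys
        c1 = enc(tiny_pp, trips, "alice", np.ones(8, dtype=int), rng)
        c2 = mkhe.multiply_plain(c1, np.full(8, 3, dtype=int), scale=4)
        with pytest.raises(mkhe.ScaleMismatch):
            mkhe.add(c1, c2)


class TestMultiply:
    def test_by_fresh_ones_is_identity(self, tiny_pp, tiny_keys, rng):
        trips, pubs = tiny_keys
        m = rng.integers(0, 1000, tiny_pp.ring.n)
        ones = np.ones(tiny_pp.ring.n, dtype=np.int64)
        ct = mkhe.multiply(
            enc(tiny_pp, trips, "alice", m, rng),
            enc(tiny_pp, trips, "bob", ones, rng),
            pubs, tiny_pp,
        )
        assert ct.mult_depth == 1
        got = mkhe.decrypt_with_secrets(ct, trips, tiny_pp)
        assert np.array_equal(got.slots, m)

    def test_by_zero_gives_zero(self, tiny_pp, tiny_keys, rng):
        trips, pubs = tiny_keys
        m = rng.integers(0, 1000, tiny_pp.ring.n)
        z = np.zeros(tiny_pp.ring.n, dtype=np.int64)
        ct = mkhe.multiply(
            enc(tiny_pp, trips, "alice", m, rng), enc(tiny_pp, trips, "bob", z, rng),
            pubs, tiny_pp,
        )
        got = mkhe.decrypt_with_secrets(ct, trips, tiny_pp)
        assert not np.any(got.slots)

    def test_cross_key_product_with_distributed_decryption(self, tiny_pp, tiny_keys, rng):
        trips, pubs = tiny_keys
        t = tiny_pp.ring.t
        m1 = rng.integers(0, 10**6, tiny_pp.ring.n)
        m2 = rng.integers(0, 10**6, tiny_pp.ring.n)
        ct = mkhe.multiply(
            enc(tiny_pp, trips, "alice", m1, rng), enc(tiny_pp, trips, "bob", m2, rng),
            pubs, tiny_pp,
        )
        shares = [mkhe.part_dec(ct, trips[p], tiny_pp, rng) for p in ct.parties]
        got = mkhe.fin_dec(ct, shares, tiny_pp)
        assert np.array_equal(
            np.asarray(got.slots, dtype=object), (m1.astype(object) * m2) % t
        )

    def test_missing_evaluation_key_rejected(self, tiny_pp, tiny_keys, rng):
        trips, pubs = tiny_keys
        c1 = enc(tiny_pp, trips, "alice", np.ones(8, dtype=int), rng)
        c2 = enc(tiny_pp, trips, "bob", np.ones(8, dtype=int), rng)
        with pytest.raises(mkhe.MissingKeyError):
            mkhe.multiply(c1, c2, {"alice": pubs["alice"]}, tiny_pp)

    def test_depth_budget_enforced(self, tiny_pp, tiny_keys, rng):
        trips, pubs = tiny_keys
        ct = enc(tiny_pp, trips, "alice", np.full(8, 2, dtype=int), rng)
        d1 = mkhe.multiply(ct, ct, pubs, tiny_pp)
        d2 = mkhe.multiply(d1, d1, pubs, tiny_pp)
        with pytest.raises(mkhe.DepthBudgetExceeded):
            mkhe.multiply(d2, ct, pubs, tiny_pp)

    def test_relinearized_product_matches_tensor_oracle(self, tiny_pp, tiny_keys, rng):
        """The relinearized ciphertext must decrypt to the same value as the
        un-relinearized tensor, evaluated directly against the secrets."""
        trips, pubs = tiny_keys
        ring = tiny_pp.ring
        m1 = rng.integers(0, 5000, ring.n)
        m2 = rng.integers(0, 5000, ring.n)
        c1 = enc(tiny_pp, trips, "alice", m1, rng)
        c2 = enc(tiny_pp, trips, "bob", m2, rng)
        # Oracle: evaluate each ciphertext at its secret (phase polynomials),
        # take the exact scaled product, then round/decode - no relinearization.
        phi1 = c1.parts[0] + c1.parts[1] * trips["alice"].sk
        phi2 = c2.parts[0] + c2.parts[1] * trips["bob"].sk
        eng = get_tensor_engine(ring)
        w = eng.scaled_product(eng.to_ext(phi1), eng.to_ext(phi2))
        c = w.to_coeffs()
        mpoly = ((c * ring.t + ring.q // 2) // ring.q) % ring.t
        from ppgc.rings import batch_decode

        oracle = batch_decode(mpoly, ring)
        got = mkhe.decrypt_with_secrets(
            mkhe.multiply(c1, c2, pubs, tiny_pp), trips, tiny_pp
        )
        assert np.array_equal(got.slots, oracle.slots)
        assert np.array_equal(
            np.asarray(got.slots, dtype=object), (m1.astype(object) * m2) % ring.t
        )

    def test_operand_order_invariance(self, tiny_pp, tiny_keys, rng):
        trips, pubs = tiny_keys
        m1 = rng.integers(0, 1000, tiny_pp.ring.n)
        m2 = rng.integers(0, 1000, tiny_pp.ring.n)
        c1 = enc(tiny_pp, trips, "alice", m1, rng)
        c2 = enc(tiny_pp, trips, "bob", m2, rng)
        g1 = mkhe.decrypt_with_secrets(mkhe.multiply(c1, c2, pubs, tiny_pp), trips, tiny_pp)
        g2 = mkhe.decrypt_with_secrets(mkhe.multiply(c2, c1, pubs, tiny_pp), trips, tiny_pp)
        assert np.array_equal(g1.slots, g2.slots)


class TestMultiplyPlain:
    def test_ones_identity_zeros_zero_random_oracle(self, tiny_pp, tiny_keys, rng):
        trips, _ = tiny_keys
        t, n = tiny_pp.ring.t, tiny_pp.ring.n
        m = rng.integers(0, t, n)
        ct = enc(tiny_pp, trips, "alice", m, rng)
        sks = {"alice": trips["alice"]}
        ones = mkhe.multiply_plain(ct, np.ones(n, dtype=np.int64))
        assert np.array_equal(mkhe.decrypt_with_secrets(ones, sks, tiny_pp).slots, m)
        zeros = mkhe.multiply_plain(ct, np.zeros(n, dtype=np.int64))
        assert not np.any(mkhe.decrypt_with_secrets(zeros, sks, tiny_pp).slots)
        p = rng.integers(0, t, n)
        got = mkhe.decrypt_with_secrets(mkhe.multiply_plain(ct, p), sks, tiny_pp)
        assert np.array_equal(
            np.asarray(got.slots, dtype=object), (m.astype(object) * p) % t
        )
        assert ones.mult_depth == ct.mult_depth


class TestDistributedDecryption:
    def test_absent_party_cannot_contribute(self, tiny_pp, tiny_keys, rng):
        trips, _ = tiny_keys
        ct = enc(tiny_pp, trips, "alice", np.ones(8, dtype=int), rng)
        with pytest.raises(mkhe.ShareError):
            mkhe.part_dec(ct, trips["bob"], tiny_pp, rng)

    def test_zero_smudging_gives_exact_share(self, tiny_pp, tiny_keys, rng):
        import dataclasses

        trips, _ = tiny_keys
        pp0 = dataclasses.replace(tiny_pp, smudge_bound=0)
        ct = enc(tiny_pp, trips, "alice", np.ones(8, dtype=int), rng)
        share = mkhe.part_dec(ct, trips["alice"], pp0, rng)
        assert share.share == ct.parts[1] * trips["alice"].sk

    def test_shares_are_randomized(self, tiny_pp, tiny_keys, rng):
        trips, _ = tiny_keys
        ct = enc(tiny_pp, trips, "alice", np.ones(8, dtype=int), rng)
        s1 = mkhe.part_dec(ct, trips["alice"], tiny_pp, rng)
        s2 = mkhe.part_dec(ct, trips["alice"], tiny_pp, rng)
        assert s1.share != s2.share

    def test_three_key_sum_equals_plaintext_sum(self, tiny_pp, tiny_keys, rng):
        trips, _ = tiny_keys
        t, n = tiny_pp.ring.t, tiny_pp.ring.n
        ms = [rng.integers(0, t, n) for _ in range(3)]
        cts = [enc(tiny_pp, trips, p, m, rng) for p, m in zip(("alice", "bob", "carol"), ms)]
        total = mkhe.add(mkhe.add(cts[0], cts[1]), cts[2])
        shares = [mkhe.part_dec(total, trips[p], tiny_pp, rng) for p in total.parties]
        got = mkhe.fin_dec(total, shares, tiny_pp)
        assert np.array_equal(got.slots, (ms[0] + ms[1] + ms[2]) % t)

    def test_missing_or_duplicate_share_rejected(self, tiny_pp, tiny_keys, rng):
        trips, _ = tiny_keys
        ct = mkhe.add(
            enc(tiny_pp, trips, "alice", np.ones(8, dtype=int), rng),
            enc(tiny_pp, trips, "bob", np.ones(8, dtype=int), rng),
        )
        sa = mkhe.part_dec(ct, trips["alice"], tiny_pp, rng)
        with pytest.raises(mkhe.ShareError):
            mkhe.fin_dec(ct, [sa], tiny_pp)
        with pytest.raises(mkhe.ShareError):
            mkhe.fin_dec(ct, [sa, sa], tiny_pp)

    def test_overdriven_noise_breaks_decoding(self, tiny_pp, tiny_keys, rng):
        """Squaring past the depth budget (with the guard lifted) must
        eventually push noise over q/(2t) and corrupt the decode."""
        import dataclasses

        trips, pubs = tiny_keys
        pp = dataclasses.replace(tiny_pp, depth_budget=16)
        t = pp.ring.t
        ct = enc(tiny_pp, trips, "alice", np.full(pp.ring.n, 3, dtype=np.int64), rng)
        expect = 3
        for _ in range(8):
            ct = mkhe.multiply(ct, ct, pubs, pp)
            expect = (expect * expect) % t
            got = mkhe.decrypt_with_secrets(ct, trips, pp)
            if not np.array_equal(got.slots, np.full(pp.ring.n, expect, dtype=object)):
                break  # noise exceeded q/(2t): decode corrupted, as predicted
        else:
            pytest.fail("decoding never failed despite unbounded squaring")


class TestNoise:
    def test_fresh_noise_below_bound(self, tiny_pp, tiny_keys, rng):
        trips, _ = tiny_keys
        ct = enc(tiny_pp, trips, "alice", rng.integers(0, 100, tiny_pp.ring.n), rng)
        bound = np.log2(tiny_pp.ring.error_tail_bound * (1 + 2 * tiny_pp.ring.n)) + 2
        assert mkhe.noise_of(ct, trips, tiny_pp) <= bound

    def test_addition_noise_triangle_inequality(self, tiny_pp, tiny_keys, rng):
        trips, _ = tiny_keys
        c1 = enc(tiny_pp, trips, "alice", rng.integers(0, 100, tiny_pp.ring.n), rng)
        c2 = enc(tiny_pp, trips, "bob", rng.integers(0, 100, tiny_pp.ring.n), rng)
        n1 = mkhe.noise_of(c1, trips, tiny_pp)
        n2 = mkhe.noise_of(c2, trips, tiny_pp)
        assert mkhe.noise_of(mkhe.add(c1, c2), trips, tiny_pp) <= max(n1, n2) + 1

    def test_multiply_noise_stays_below_threshold(self, tiny_pp, tiny_keys, rng):
        trips, pubs = tiny_keys
        for _ in range(5):
            c1 = enc(tiny_pp, trips, "alice", rng.integers(0, 1000, tiny_pp.ring.n), rng)
            c2 = enc(tiny_pp, trips, "bob", rng.integers(0, 1000, tiny_pp.ring.n), rng)
            ct = mkhe.multiply(c1, c2, pubs, tiny_pp)
            assert mkhe.noise_of(ct, trips, tiny_pp) < mkhe.decryption_threshold_bits(tiny_pp)


class TestSerialization:
    def test_round_trips(self, tiny_pp, tiny_keys, rng, tmp_path):
        trips, _ = tiny_keys
        serialize.save_params(tiny_pp, tmp_path / "pp.json")
        pp2 = serialize.load_params(tmp_path / "pp.json")
        assert pp2.fingerprint() == tiny_pp.fingerprint()
        blob = serialize.public_key_to_bytes(trips["alice"].public, tiny_pp)
        pub = serialize.public_key_from_bytes(blob, tiny_pp)
        assert pub.b[0] == trips["alice"].public.b[0]
        ct = enc(tiny_pp, trips, "alice", np.arange(16) % 7, rng)
        ct2 = serialize.ciphertext_from_bytes(
            serialize.ciphertext_to_bytes(ct, tiny_pp), tiny_pp
        )
        assert ct2.parts[0] == ct.parts[0] and ct2.parties == ct.parties
        share = mkhe.part_dec(ct, trips["alice"], tiny_pp, rng)
        s2 = serialize.share_from_bytes(serialize.share_to_bytes(share, tiny_pp), tiny_pp)
        assert s2.share == share.share

    def test_foreign_parameters_rejected(self, tiny_pp, tiny_keys, rng):
        trips, _ = tiny_keys
        other = mkhe.setup("tiny", seed=999)
        blob = serialize.public_key_to_bytes(trips["alice"].public, tiny_pp)
        with pytest.raises(serialize.SerializationError):
            serialize.public_key_from_bytes(blob, other)
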