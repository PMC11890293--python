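"""On-disk / on-wire format for keys, ciphertexts, and decryption shares.

A length-prefixed binary container: magic ``PPGC1``, a JSON header carrying
the kind, the public-parameter fingerprint and metadata, then the ring
elements as fixed-width big-endian coefficient blocks.  Every load checks the
fingerprint so material from a different parameter set is rejected.  The CRS
always travels as a seed inside the parameter file, never as polynomials.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np

from .mkhe import Ciphertext, KeyTriple, PartialDecryption, PublicKey, PublicParams
from .profiles import load_profile, profile_dict
from .rings import RingElement, RingParams

MAGIC = b"PPGC1"


class SerializationError(ValueError):
    pass


def _coeff_width(params: RingParams) -> int:
    return (params.q.bit_length() + 7) // 8


def _pack_elements(elems, params: RingParams) -> bytes:
    w = _coeff_width(params)
    out = bytearray()
    for e in elems:
        for c in e.to_coeffs():
            out += int(c).to_bytes(w, "big")
    return bytes(out)


def _unpack_elements(blob: bytes, count: int, params: RingParams) -> list:
    w = _coeff_width(params)
    n = params.n
    if len(blob) != count * n * w:
        raise SerializationError("payload size does not match element count")
    elems = []
    pos = 0
    for _ in range(count):
        coeffs = [int.from_bytes(blob[pos + i * w : pos + (i + 1) * w], "big") for i in range(n)]
        pos += n * w
        elems.append(RingElement.from_coeffs(params, coeffs))
    return elems


def _container(kind: str, header: dict, payload: bytes) -> bytes:
    head = json.dumps({"kind": kind, **header}).encode()
    return MAGIC + struct.pack(">I", len(head)) + head + payload


def _open_container(data: bytes, expect_kind: str, pp: PublicParams | None) -> tuple:
    if data[:5] != MAGIC:
        raise SerializationError("not a PPGC container")
    (hlen,) = struct.unpack(">I", data[5:9])
    header = json.loads(data[9 : 9 + hlen].decode())
    if header.get("kind") != expect_kind:
        raise SerializationError(f"expected {expect_kind!r}, found {header.get('kind')!r}")
    if pp is not None and header.get("fingerprint") != pp.fingerprint():
        raise SerializationError("parameter fingerprint mismatch")
    return header, data[9 + hlen :]


# -- public parameters (pure JSON, no ring elements) ------------------------


def params_to_json(pp: PublicParams) -> str:
    d = profile_dict(pp.ring, pp.crs_seed, pp.profile)
    d.update(
        {
            "smudge_bound": pp.smudge_bound,
            "depth_budget": pp.depth_budget,
            "fingerprint": pp.fingerprint(),
        }
    )
    return json.dumps(d, indent=1)


def save_params(pp: PublicParams, path) -> None:
    Path(path).write_text(params_to_json(pp))


def load_params(path) -> PublicParams:
    d = json.loads(Path(path).read_text())
    ring, crs_seed = load_profile(path)
    pp = PublicParams(
        ring=ring,
        crs_seed=crs_seed,
        smudge_bound=d.get("smudge_bound", 1 << 40),
        depth_budget=d.get("depth_budget", 2),
        profile=d.get("profile", ""),
    )
    if "fingerprint" in d and d["fingerprint"] != pp.fingerprint():
        raise SerializationError("parameter file fingerprint mismatch")
    return pp


# -- keys -------------------------------------------------------------------


def public_key_to_bytes(pub: PublicKey, pp: PublicParams) -> bytes:
    d = len(pub.b)
    elems = list(pub.b) + list(pub.d0) + list(pub.d1) + list(pub.d2)
    header = {"fingerprint": pp.fingerprint(), "party_id": pub.party_id, "digits": d}
    return _container("public_key", header, _pack_elements(elems, pp.ring))


def public_key_from_bytes(data: bytes, pp: PublicParams) -> PublicKey:
    header, blob = _open_container(data, "public_key", pp)
    d = header["digits"]
    elems = _unpack_elements(blob, 4 * d, pp.ring)
    return PublicKey(
        party_id=header["party_id"],
        b=tuple(elems[:d]),
        d0=tuple(elems[d : 2 * d]),
        d1=tuple(elems[2 * d : 3 * d]),
        d2=tuple(elems[3 * d : 4 * d]),
    )


def secret_key_to_bytes(key: KeyTriple, pp: PublicParams) -> bytes:
    header = {"fingerprint": pp.fingerprint(), "party_id": key.party_id}
    return _container("secret_key", header, _pack_elements([key.sk], pp.ring))


def secret_key_from_bytes(data: bytes, pp: PublicParams, public: PublicKey) -> KeyTriple:
    header, blob = _open_container(data, "secret_key", pp)
    (sk,) = _unpack_elements(blob, 1, pp.ring)
    if header["party_id"] != public.party_id:
        raise SerializationError("secret/public key party mismatch")
    return KeyTriple(party_id=header["party_id"], sk=sk, public=public)


# -- ciphertexts and shares -------------------------------------------------


def ciphertext_to_bytes(ct: Ciphertext, pp: PublicParams) -> bytes:
    header = {
        "fingerprint": pp.fingerprint(),
        "parties": list(ct.parties),
        "mult_depth": ct.mult_depth,
        "plain_scale": ct.plain_scale,
    }
    return _container("ciphertext", header, _pack_elements(ct.parts, pp.ring))


def ciphertext_from_bytes(data: bytes, pp: PublicParams) -> Ciphertext:
    header, blob = _open_container(data, "ciphertext", pp)
    parties = tuple(header["parties"])
    parts = _unpack_elements(blob, len(parties) + 1, pp.ring)
    return Ciphertext(
        tuple(parts), parties, header["mult_depth"], header["plain_scale"]
    )


def share_to_bytes(share: PartialDecryption, pp: PublicParams) -> bytes:
    header = {"fingerprint": pp.fingerprint(), "party_id": share.party_id}
    return _container("partial_decryption", header, _pack_elements([share.share], pp.ring))


def share_from_bytes(data: bytes, pp: PublicParams) -> PartialDecryption:
    header, blob = _open_container(data, "partial_decryption", pp)
    (elem,) = _unpack_elements(blob, 1, pp.ring)
    return PartialDecryption(party_id=header["party_id"], share=elem)
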