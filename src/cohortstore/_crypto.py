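"""At-rest record encryption: AES-256 in GCM mode, pure Python.

Every column/mask record in a store is gzip-compressed and then sealed as an
independent AES-GCM record (``nonce || ciphertext || tag``).  The
implementation below is self-contained: an encrypt-direction AES-256 with
precomputed T-tables and a GHASH using per-key 8-bit multiplication tables.
Throughput is a few hundred KiB/s, which is ample for desk-scale stores where
individual records are small and access is lazy.

Authentication failure on decryption always raises
:class:`AuthenticationError`; plaintext is never returned from a record whose
tag does not verify.
"""

from __future__ import annotations

import gzip
import os

KEY_BYTES = 32
NONCE_BYTES = 12
TAG_BYTES = 16


class AuthenticationError(ValueError):
    """Decryption failed: wrong key or corrupted record."""


# ---------------------------------------------------------------------------
# AES-256 block cipher (encrypt direction only; GCM never decrypts blocks)
# ---------------------------------------------------------------------------

def _build_tables():
    # S-box from GF(2^8) inversion + affine map, so no hardcoded constants
    # beyond the field polynomial 0x11B and the 0x63 affine offset.
    exp = [0] * 256
    log = [0] * 256
    x = 1
    for i in range(255):
        exp[i] = x
        log[x] = i
        x = (x ^ (x << 1) ^ (0x1B if x & 0x80 else 0)) & 0xFF  # x *= 3
    sbox = [0] * 256
    for i in range(256):
        inv = 0 if i == 0 else exp[(255 - log[i]) % 255]
        s = inv
        for _ in range(4):
            inv = ((inv << 1) | (inv >> 7)) & 0xFF
            s ^= inv
        sbox[i] = s ^ 0x63

    def xtime(a):
        return ((a << 1) ^ 0x1B) & 0xFF if a & 0x80 else a << 1

    te0 = [0] * 256
    for i, s in enumerate(sbox):
        s2 = xtime(s)
        te0[i] = (s2 << 24) | (s << 16) | (s << 8) | (s2 ^ s)
    te1 = [((t >> 8) | ((t & 0xFF) << 24)) & 0xFFFFFFFF for t in te0]
    te2 = [((t >> 8) | ((t & 0xFF) << 24)) & 0xFFFFFFFF for t in te1]
    te3 = [((t >> 8) | ((t & 0xFF) << 24)) & 0xFFFFFFFF for t in te2]
    return sbox, te0, te1, te2, te3


_SBOX, _TE0, _TE1, _TE2, _TE3 = _build_tables()

_RCON = [0x01, 0x02, 0x04, 0x08, 0x10, 0x20, 0x40, 0x80, 0x1B, 0x36]


def _expand_key(key: bytes) -> list[int]:
    # AES-256: 8-word key, 15 round keys (60 words)
    w = [int.from_bytes(key[i: i + 4], "big") for i in range(0, 32, 4)]
    for i in range(8, 60):
        t = w[i - 1]
        if i % 8 == 0:
            t = ((t << 8) | (t >> 24)) & 0xFFFFFFFF  # RotWord
            t = (
                (_SBOX[(t >> 24) & 0xFF] << 24)
                | (_SBOX[(t >> 16) & 0xFF] << 16)
                | (_SBOX[(t >> 8) & 0xFF] << 8)
                | _SBOX[t & 0xFF]
            )
            t ^= _RCON[i // 8 - 1] << 24
        elif i % 8 == 4:
            t = (
                (_SBOX[(t >> 24) & 0xFF] << 24)
                | (_SBOX[(t >> 16) & 0xFF] << 16)
                | (_SBOX[(t >> 8) & 0xFF] << 8)
                | _SBOX[t & 0xFF]
            )
        w.append(w[i - 8] ^ t)
    return w


def _encrypt_block(rk: list[int], block16: bytes) -> bytes:
    te0, te1, te2, te3, sbox = _TE0, _TE1, _TE2, _TE3, _SBOX
    s0 = int.from_bytes(block16[0:4], "big") ^ rk[0]
    s1 = int.from_bytes(block16[4:8], "big") ^ rk[1]
    s2 = int.from_bytes(block16[8:12], "big") ^ rk[2]
    s3 = int.from_bytes(block16[12:16], "big") ^ rk[3]
    k = 4
    for _ in range(13):  # 13 full rounds, final round below
        t0 = (
            te0[s0 >> 24]
            ^ te1[(s1 >> 16) & 0xFF]
            ^ te2[(s2 >> 8) & 0xFF]
            ^ te3[s3 & 0xFF]
            ^ rk[k]
        )
        t1 = (
            te0[s1 >> 24]
            ^ te1[(s2 >> 16) & 0xFF]
            ^ te2[(s3 >> 8) & 0xFF]
            ^ te3[s0 & 0xFF]
            ^ rk[k + 1]
        )
        t2 = (
            te0[s2 >> 24]
            ^ te1[(s3 >> 16) & 0xFF]
            ^ te2[(s0 >> 8) & 0xFF]
            ^ te3[s1 & 0xFF]
            ^ rk[k + 2]
        )
        t3 = (
            te0[s3 >> 24]
            ^ te1[(s0 >> 16) & 0xFF]
            ^ te2[(s1 >> 8) & 0xFF]
            ^ te3[s2 & 0xFF]
            ^ rk[k + 3]
        )
        s0, s1, s2, s3 = t0, t1, t2, t3
        k += 4
    out = bytearray(16)
    for i, (a, b, c, d) in enumerate(((s0, s1, s2, s3), (s1, s2, s3, s0),
                                      (s2, s3, s0, s1), (s3, s0, s1, s2))):
        w = (
            (sbox[a >> 24] << 24)
            | (sbox[(b >> 16) & 0xFF] << 16)
            | (sbox[(c >> 8) & 0xFF] << 8)
            | sbox[d & 0xFF]
        ) ^ rk[k + i]
        out[4 * i: 4 * i + 4] = w.to_bytes(4, "big")
    return bytes(out)


# ---------------------------------------------------------------------------
# GHASH over GF(2^128) with the GCM bit convention
# ---------------------------------------------------------------------------

_R = 0xE1000000000000000000000000000000


def _gf_shift(v: int) -> int:
    # multiply by x in the GCM (reflected) representation
    return (v >> 1) ^ _R if v & 1 else v >> 1


def _build_ghash_tables(h: int):
    # P[k] = x^k * H; byte tables T[j][b] give (b at byte j) * H
    p = [0] * 128
    p[0] = h
    for k in range(1, 128):
        p[k] = _gf_shift(p[k - 1])
    tables = []
    for j in range(16):
        t = [0] * 256
        for i in range(8):
            t[1 << i] = p[127 - (8 * j + i)]
        for b in range(1, 256):
            if b & (b - 1):
                t[b] = t[b & (b - 1)] ^ t[b & -b]
        tables.append(t)
    return tables


class _Gcm:
    """Per-key AES-GCM state (round keys + GHASH tables), cached by key."""

    def __init__(self, key: bytes):
        if len(key) != KEY_BYTES:
            raise ValueError(
                f"key must be exactly {KEY_BYTES} bytes, got {len(key)}"
            )
        self._rk = _expand_key(key)
        h = int.from_bytes(_encrypt_block(self._rk, b"\x00" * 16), "big")
        self._ghash_tables = _build_ghash_tables(h)

    def _ghash(self, data: bytes, lengths_block: bytes) -> int:
        tables = self._ghash_tables
        z = 0
        n = len(data)
        for off in range(0, n, 16):
            block = data[off: off + 16]
            if len(block) < 16:
                block = block + b"\x00" * (16 - len(block))
            z ^= int.from_bytes(block, "big")
            acc = 0
            for j in range(16):
                acc ^= tables[j][(z >> (8 * j)) & 0xFF]
            z = acc
        z ^= int.from_bytes(lengths_block, "big")
        acc = 0
        for j in range(16):
            acc ^= tables[j][(z >> (8 * j)) & 0xFF]
        return acc

    def _keystream_xor(self, nonce: bytes, data: bytes) -> bytes:
        rk = self._rk
        prefix = nonce  # 96-bit nonce: J0 = nonce || 0x00000001
        out = bytearray(len(data))
        ctr = 1
        for off in range(0, len(data), 16):
            ctr += 1
            ks = _encrypt_block(rk, prefix + ctr.to_bytes(4, "big"))
            chunk = data[off: off + 16]
            out[off: off + len(chunk)] = (
                int.from_bytes(chunk, "big")
                ^ int.from_bytes(ks[: len(chunk)], "big")
            ).to_bytes(len(chunk), "big")
        return bytes(out)

    def _tag(self, nonce: bytes, ciphertext: bytes, aad: bytes) -> bytes:
        # GHASH(A || pad || C || pad || len64(A) || len64(C)), then E(K, J0)
        apad = aad + b"\x00" * (-len(aad) % 16)
        lengths = (len(aad) * 8).to_bytes(8, "big") + (
            len(ciphertext) * 8
        ).to_bytes(8, "big")
        s = self._ghash(apad + ciphertext + b"\x00" * (-len(ciphertext) % 16),
                        lengths)
        ek_j0 = _encrypt_block(self._rk, nonce + b"\x00\x00\x00\x01")
        return (s ^ int.from_bytes(ek_j0, "big")).to_bytes(16, "big")

    def encrypt(self, nonce: bytes, plaintext: bytes, aad: bytes = b""):
        if len(nonce) != NONCE_BYTES:
            raise ValueError("nonce must be 12 bytes")
        ct = self._keystream_xor(nonce, plaintext)
        return ct, self._tag(nonce, ct, aad)

    def decrypt(self, nonce: bytes, ciphertext: bytes, tag: bytes,
                aad: bytes = b"") -> bytes:
        expect = self._tag(nonce, ciphertext, aad)
        # constant-time-ish comparison; leakage is irrelevant at desk scale
        # but there is no reason to hand an attacker a timing oracle either
        diff = 0
        for a, b in zip(expect, tag):
            diff |= a ^ b
        if diff or len(tag) != TAG_BYTES:
            raise AuthenticationError("bad key or corrupted store")
        return self._keystream_xor(nonce, ciphertext)


_CIPHER_CACHE: dict[bytes, _Gcm] = {}


def _cipher(key: bytes) -> _Gcm:
    c = _CIPHER_CACHE.get(key)
    if c is None:
        c = _CIPHER_CACHE[key] = _Gcm(key)
    return c


# ---------------------------------------------------------------------------
# Record layer: gzip then encrypt
# ---------------------------------------------------------------------------

def seal_record(key: bytes, plaintext: bytes, aad: bytes = b"") -> bytes:
    """Compress and encrypt one record: ``nonce || ciphertext || tag``.

    A fresh random 96-bit nonce is drawn per record; gzip runs with mtime=0
    so that the pre-encryption bytes are deterministic.
    """
    nonce = os.urandom(NONCE_BYTES)
    compressed = gzip.compress(plaintext, mtime=0)
    ct, tag = _cipher(key).encrypt(nonce, compressed, aad)
    return nonce + ct + tag


def open_record(key: bytes, record: bytes, aad: bytes = b"") -> bytes:
    """Decrypt and decompress a sealed record, authenticating first."""
    if len(record) < NONCE_BYTES + TAG_BYTES:
        raise AuthenticationError("bad key or corrupted store")
    nonce = record[:NONCE_BYTES]
    ct = record[NONCE_BYTES:-TAG_BYTES]
    tag = record[-TAG_BYTES:]
    compressed = _cipher(key).decrypt(nonce, ct, tag, aad)
    try:
        return gzip.decompress(compressed)
    except OSError as exc:  # authenticated but undecompressable: corruption
        raise AuthenticationError(f"corrupted record payload: {exc}") from exc


def encrypt_block(key: bytes, block16: bytes) -> bytes:
    """Raw single-block AES-256 encryption (exposed for validation)."""
    return _encrypt_block(_cipher(key)._rk, block16)


def gcm_encrypt(key: bytes, nonce: bytes, plaintext: bytes,
                aad: bytes = b"") -> tuple[bytes, bytes]:
    """Raw AES-256-GCM (no compression): returns (ciphertext, tag)."""
    return _cipher(key).encrypt(nonce, plaintext, aad)


def load_key(path) -> bytes:
    """Read a 256-bit key file: either 32 raw bytes or 64 hex characters."""
    with open(path, "rb") as fh:
        raw = fh.read()
    stripped = raw.strip()
    if len(stripped) == 2 * KEY_BYTES:
        try:
            return bytes.fromhex(stripped.decode("ascii"))
        except (UnicodeDecodeError, ValueError):
            pass
    if len(raw) == KEY_BYTES:
        return raw
    raise ValueError(
        f"key file must hold {KEY_BYTES} raw bytes or {2 * KEY_BYTES} hex "
        f"characters, got {len(raw)} bytes"
    )
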