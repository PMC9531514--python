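"""Packed bit-vector primitives.

Fingerprints are stored bit-packed (``uint8``, 8 bits per byte, big-endian
within each byte as produced by :func:`numpy.packbits`).  All Tanimoto
arithmetic runs on the packed form via ``np.bitwise_count``, which keeps a
15,000-conformer class at ~2 MB instead of ~2 GB of booleans.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError

# rows per block in pairwise kernels; bounds peak memory at
# block * n_cols * n_bytes uint8 intermediates (~64 MB at 15k cols, 1024 bits)
_BLOCK = 32


def pack_bits(bits: np.ndarray) -> np.ndarray:
    """Pack a boolean array (n, n_bits) into (n, n_bits // 8) uint8."""
    bits = np.asarray(bits)
    if bits.ndim == 1:
        bits = bits[None, :]
    if bits.shape[1] % 8 != 0:
        raise ConfigurationError("bit length must be a multiple of 8")
    return np.packbits(bits.astype(np.uint8), axis=1)


def unpack_bits(packed: np.ndarray, n_bits: int) -> np.ndarray:
    """Inverse of :func:`pack_bits`; returns a boolean array (n, n_bits)."""
    return np.unpackbits(packed, axis=-1, count=n_bits).astype(bool)


def popcount(packed: np.ndarray) -> np.ndarray:
    """Number of set bits per row of a packed array."""
    return np.bitwise_count(packed).sum(axis=-1, dtype=np.int64)


def to_hex(packed_row: np.ndarray) -> str:
    return bytes(packed_row.tobytes()).hex()


def from_hex(hex_str: str) -> np.ndarray:
    return np.frombuffer(bytes.fromhex(hex_str), dtype=np.uint8)


def tanimoto_packed(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard-Tanimoto coefficient of two packed rows; 0/0 defined as 0."""
    if a.shape != b.shape:
        raise ConfigurationError(
            f"fingerprint length mismatch: {a.shape} vs {b.shape}"
        )
    inter = int(np.bitwise_count(a & b).sum())
    union = int(np.bitwise_count(a | b).sum())
    return inter / union if union else 0.0


def tanimoto_cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """All-pairs Tanimoto matrix (n_a, n_b) between two packed stacks."""
    if a.shape[-1] != b.shape[-1]:
        raise ConfigurationError("fingerprint length mismatch")
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    pop_a = popcount(a)
    pop_b = popcount(b)
    out = np.empty((a.shape[0], b.shape[0]), dtype=np.float64)
    for start in range(0, a.shape[0], _BLOCK):
        stop = min(start + _BLOCK, a.shape[0])
        inter = np.bitwise_count(a[start:stop, None, :] & b[None, :, :]).sum(
            axis=-1, dtype=np.int64
        )
        union = pop_a[start:stop, None] + pop_b[None, :] - inter
        blk = out[start:stop]
        np.divide(inter, union, out=blk, where=union > 0)
        blk[union == 0] = 0.0
    return out


def tanimoto_condensed(packed: np.ndarray) -> np.ndarray:
    """Upper-triangle (i < j) pooled Tanimoto scores of one packed stack.

    Self-pairs are excluded by construction; output length is n(n-1)/2 in
    row-major (i, j>i) order.
    """
    n = packed.shape[0]
    pop = popcount(packed)
    chunks = []
    for i in range(0, n, _BLOCK):
        j = min(i + _BLOCK, n)
        inter = np.bitwise_count(packed[i:j, None, :] & packed[None, i:, :]).sum(
            axis=-1, dtype=np.int64
        )
        union = pop[i:j, None] + pop[None, i:] - inter
        sim = np.zeros_like(inter, dtype=np.float64)
        np.divide(inter, union, out=sim, where=union > 0)
        # keep strictly-upper part relative to global indices: block row r
        # (global i+r) pairs with global columns > i+r, i.e. local cols > r
        for r in range(j - i):
            chunks.append(sim[r, r + 1 :])
    return np.concatenate(chunks) if chunks else np.empty(0)
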