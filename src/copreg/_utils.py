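"""Shared helpers: DNA encoding, circular coordinate arithmetic, seeded sub-streams."""

from __future__ import annotations

import zlib

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# IUPAC degenerate alphabet (DNA)
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to int8 indices; A,C,G,T -> 0..3, anything else -> 4 (N)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, idx in BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def decode(indices: np.ndarray) -> str:
    return "".join("ACGTN"[i] for i in indices)


def circular_slice(seq: str, start: int, length: int) -> str:
    """Slice `length` characters starting at `start` (mod len) with wraparound."""
    n = len(seq)
    if length < 0:
        raise ValueError("length must be non-negative")
    if length > n:
        raise ValueError("slice longer than sequence")
    start %= n
    end = start + length
    if end <= n:
        return seq[start:end]
    return seq[start:] + seq[: end - n]


def iupac_matches(base: str, code: str) -> bool:
    return base.upper() in IUPAC[code.upper()]


def _key_to_int(key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0x7FFFFFFF
    return zlib.crc32(str(key).encode("utf-8"))


def sub_rng(seed: int, *keys) -> np.random.Generator:
    """Independent, reproducible sub-stream derived from a master seed and stream keys.

    Strings are hashed with crc32 so replicate/sample labels can key streams.
    """
    entropy = [int(seed) & 0x7FFFFFFF] + [_key_to_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))
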