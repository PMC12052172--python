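"""Nucleotide-sequence helpers shared across modules.

Sequences are plain upper-case strings over {A,C,G,T,N}; hot paths work on
uint8 index arrays (A=0, C=1, G=2, T=3).
"""
from __future__ import annotations

import numpy as np

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lower case
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP_IDX = np.array([3, 2, 1, 0], dtype=np.uint8)
_COMP_TABLE = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")
VALID_ALPHABET = set("ACGTNacgtn")


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 index array; rejects N and other symbols."""
    idx = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (idx == 255).any():
        bad = sorted({c for c in seq if c.upper() not in "ACGT"})
        raise ValueError(f"sequence contains non-ACGT symbols: {bad}")
    return idx


def decode(idx: np.ndarray) -> str:
    return _BASES[idx].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP_TABLE)[::-1]


def revcomp_idx(idx: np.ndarray) -> np.ndarray:
    return _COMP_IDX[idx][::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    g = seq.count("G") + seq.count("g") + seq.count("C") + seq.count("c")
    return g / len(seq)


def validate_alphabet(seq: str) -> None:
    bad = set(seq) - VALID_ALPHABET
    if bad:
        raise ValueError(f"sequence contains invalid symbols: {sorted(bad)}")


def find_motif(seq: str, motif: str) -> list[int]:
    """All (possibly overlapping) exact forward-strand occurrences of motif.

    'N' in the subject never matches because comparison is literal.
    """
    positions = []
    start = seq.find(motif)
    while start != -1:
        positions.append(start)
        start = seq.find(motif, start + 1)
    return positions


def random_sequence(n: int, gc: float, rng: np.random.Generator) -> str:
    """Random i.i.d. sequence with expected GC content ``gc``."""
    at = (1.0 - gc) / 2.0
    p = np.array([at, gc / 2.0, gc / 2.0, at])
    idx = rng.choice(4, size=n, p=p).astype(np.uint8)
    return decode(idx)


def mutate_idx(
    idx: np.ndarray,
    sub_rate: float,
    ins_rate: float,
    del_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Apply independent per-base substitutions, insertions and deletions.

    Insertions place one random base after the position they are drawn at
    (after the original base if it survives deletion, in its place otherwise).
    Returns the mutated index array and the number of matching bases
    (kept and not substituted), which seeds alignment identity bookkeeping.
    """
    n = len(idx)
    if n == 0:
        return idx.copy(), 0
    out = idx.copy()
    sub_mask = rng.random(n) < sub_rate
    nsub = int(sub_mask.sum())
    if nsub:
        shift = rng.integers(1, 4, size=nsub).astype(np.uint8)
        out[sub_mask] = (out[sub_mask] + shift) % 4
    del_mask = rng.random(n) < del_rate if del_rate > 0 else np.zeros(n, dtype=bool)
    ins_mask = rng.random(n) < ins_rate if ins_rate > 0 else np.zeros(n, dtype=bool)
    counts = (~del_mask).astype(np.int64) + ins_mask
    res = np.repeat(out, counts)
    n_ins = int(ins_mask.sum())
    if n_ins:
        ends = np.cumsum(counts)
        slots = ends[ins_mask] - 1
        res[slots] = rng.integers(0, 4, size=n_ins).astype(np.uint8)
    n_match = int((~del_mask & ~sub_mask).sum())
    return res, n_match
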