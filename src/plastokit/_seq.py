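"""Low-level DNA sequence helpers shared across modules.

Coordinates are 0-based half-open everywhere inside the package; conversion
to 1-based inclusive happens only at format boundaries (GFF3, GenBank, SAM).
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# base -> 2-bit code; anything non-ACGT maps to 255 (invalid)
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to uint8 codes (A=0,C=1,G=2,T=3, other=255)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join("ACGT"[c] for c in codes)


def kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes of all k-mers of ``seq``.

    Returns ``(codes, valid)`` where ``codes[i]`` encodes ``seq[i:i+k]`` in
    2 bits per base (first base most significant) and ``valid[i]`` is False
    when the window contains a non-ACGT character.  Requires ``2*k <= 63``.
    """
    if k < 1 or 2 * k > 63:
        raise ValueError(f"k={k} out of supported range")
    vals = encode(seq)
    n = len(vals) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(vals, k)
    valid = ~(win == 255).any(axis=1)
    w = win.astype(np.uint64).copy()
    w[w == 255] = 0
    powers = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    codes = (w * powers).sum(axis=1, dtype=np.uint64)
    return codes, valid


def kmer_rc_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Codes of the reverse complement of each k-mer window of ``seq``."""
    vals = encode(seq)
    n = len(vals) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(vals, k)
    valid = ~(win == 255).any(axis=1)
    w = win.astype(np.uint64).copy()
    w[w == 255] = 0
    comp = np.uint64(3) - w
    powers = (np.uint64(4) ** np.arange(k, dtype=np.uint64))  # reversed order
    codes = (comp * powers).sum(axis=1, dtype=np.uint64)
    return codes, valid


def canonical_kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Strand-collapsed (min of forward/revcomp) codes per window."""
    fwd, valid = kmer_codes(seq, k)
    rc, _ = kmer_rc_codes(seq, k)
    return np.minimum(fwd, rc), valid


def random_seq_exact_gc(rng: np.random.Generator, length: int, gc: float) -> str:
    """Random sequence whose G+C count is exactly ``round(length*gc)``.

    Sampling composition exactly (rather than per-base Bernoulli) keeps the
    realised GC of even short regions on target.
    """
    n_gc = int(round(length * gc))
    n_at = length - n_gc
    g = rng.integers(0, 2, size=n_gc)  # split GC into G/C uniformly
    a = rng.integers(0, 2, size=n_at)
    arr = np.concatenate([np.where(g == 0, 2, 1), np.where(a == 0, 0, 3)]).astype(np.uint8)
    rng.shuffle(arr)
    return decode(arr)


def gc_percent(seq: str) -> float:
    """GC% of a sequence, case-insensitive, N excluded from both counts."""
    vals = encode(seq)
    acgt = vals != 255
    denom = int(acgt.sum())
    if denom == 0:
        return 0.0
    gc = int(((vals == 1) | (vals == 2)).sum())
    return 100.0 * gc / denom


def rotate(seq: str, offset: int) -> str:
    """Rotate a circular sequence so that ``offset`` becomes position 0."""
    offset %= len(seq)
    return seq[offset:] + seq[:offset]
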