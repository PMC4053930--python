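"""Low-level k-mer machinery shared by the assembler, mapper and evaluators.

Sequences are plain ACGT strings at the API surface.  Internally, k-mers of
size <= 31 are packed 2 bits/base into uint64 for fast counting with numpy;
longer k-mers fall back to a pure-string path.
"""

from __future__ import annotations

import numpy as np

try:  # numba accelerates the packing kernels; the numpy path is equivalent
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f

        return deco if not (len(a) == 1 and callable(a[0])) else a[0]

_COMP = str.maketrans("ACGTN", "TGCAN")

# byte-code lookup: A,C,G,T -> 0..3, N -> 4, everything else -> 255
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[ord(chr(_b).lower())] = _i
_CODE[ord("N")] = 4
_CODE[ord("n")] = 4

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def canonical(seq: str) -> str:
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def encode_seq(seq: str) -> np.ndarray:
    """Base codes (A=0 C=1 G=2 T=3, N=4) for a sequence; rejects other chars."""
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.max(initial=0) == 255:
        bad = seq[int(np.argmax(codes == 255))]
        raise ValueError(f"non-ACGTN character {bad!r} in sequence")
    return codes


def _window_ints(codes: np.ndarray, k: int) -> np.ndarray:
    """Packed uint64 for every k-window of a code array.

    Windows containing N (code 4) produce garbage values; callers mask
    them out with a validity test.
    """
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.uint64)
    c = (codes & 3).astype(np.uint64)
    out = np.zeros(n - k + 1, dtype=np.uint64)
    for j in range(k):
        out += c[j : j + n - k + 1] << np.uint64(2 * (k - 1 - j))
    return out


def canonical_kmer_ints(codes: np.ndarray, k: int) -> np.ndarray:
    """Canonical packed k-mers of an N-free code run (k <= 31)."""
    fwd = _window_ints(codes, k)
    if len(fwd) == 0:
        return fwd
    rc = _window_ints((3 - codes)[::-1], k)[::-1]
    return np.minimum(fwd, rc)


def iter_acgt_runs(codes: np.ndarray):
    """Yield maximal N-free sub-arrays of a code array."""
    if len(codes) == 0:
        return
    is_n = codes == 4
    if not is_n.any():
        yield codes
        return
    breaks = np.flatnonzero(is_n)
    start = 0
    for b in breaks:
        if b > start:
            yield codes[start:b]
        start = b + 1
    if start < len(codes):
        yield codes[start:]


def decode_ints(ints: np.ndarray, k: int) -> list[str]:
    """Unpack uint64 k-mers back to strings."""
    n = len(ints)
    if n == 0:
        return []
    out = np.empty((n, k), dtype=np.uint8)
    vals = ints.copy()
    for j in range(k - 1, -1, -1):
        out[:, j] = _BASES[(vals & np.uint64(3)).astype(np.intp)]
        vals >>= np.uint64(2)
    flat = out.tobytes()
    return [flat[i * k : (i + 1) * k].decode("ascii") for i in range(n)]


@njit(cache=False)
def _rolling_canonical(codes, k):  # pragma: no cover - exercised via wrapper
    """Canonical packed k-mers in one rolling pass; N (code 4) resets."""
    n = codes.shape[0]
    out = np.empty(n, dtype=np.uint64)
    mask = np.uint64((1 << (2 * k)) - 1)
    shift = np.uint64(2 * (k - 1))
    fwd = np.uint64(0)
    rc = np.uint64(0)
    run = 0
    m = 0
    for i in range(n):
        c = codes[i]
        if c > 3:
            run = 0
            fwd = np.uint64(0)
            rc = np.uint64(0)
            continue
        fwd = ((fwd << np.uint64(2)) | np.uint64(c)) & mask
        rc = (rc >> np.uint64(2)) | (np.uint64(3 - c) << shift)
        run += 1
        if run >= k:
            out[m] = fwd if fwd <= rc else rc
            m += 1
    return out[:m]


def _canonical_ints_batch(codes: np.ndarray, k: int) -> np.ndarray:
    """All valid canonical packed k-mers of a code array (N-aware)."""
    if _HAVE_NUMBA:
        return _rolling_canonical(codes, k)
    fwd = _window_ints(codes, k)
    rc = _window_ints(((3 - codes.astype(np.int16)) % 5).astype(np.uint8)[::-1], k)[::-1]
    has_n = (codes == 4).astype(np.int32)
    bad = np.convolve(has_n, np.ones(k, dtype=np.int32), "valid") > 0
    return np.minimum(fwd[~bad], rc[~bad])


def count_canonical_kmers(reads, k: int) -> tuple[dict, int]:
    """Count canonical k-mers across an iterable of sequences.

    Returns (counts dict keyed by k-mer string, shortest read length seen).
    """
    shortest = None
    if k <= 31:
        # batch all sequences into one code array with N sentinels between
        # reads so one vectorized pass covers everything
        parts = []
        for seq in reads:
            shortest = len(seq) if shortest is None else min(shortest, len(seq))
            parts.append(seq)
        if not parts:
            return {}, 0
        codes = encode_seq("N".join(parts))
        allk = _canonical_ints_batch(codes, k)
        if len(allk) == 0:
            return {}, (shortest or 0)
        uniq, cnt = np.unique(allk, return_counts=True)
        keys = decode_ints(uniq, k)
        return dict(zip(keys, cnt.tolist())), (shortest or 0)
    # string fallback for large k (e.g. the k=64 real-data setting)
    counts: dict[str, int] = {}
    for seq in reads:
        shortest = len(seq) if shortest is None else min(shortest, len(seq))
        s = seq.upper()
        for i in range(len(s) - k + 1):
            km = s[i : i + k]
            if "N" in km:
                continue
            km = canonical(km)
            counts[km] = counts.get(km, 0) + 1
    return counts, (shortest or 0)
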