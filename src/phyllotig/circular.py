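"""Circular-contig detection by terminal sequence overlap.

An assembler emits a closed (circular) replicon as a linear string whose start
is repeated at the end. Circularity is therefore called when a long prefix of
the contig matches its suffix within a small substitution tolerance. The scan
is longest-overlap-wins: candidate overlap lengths are considered from
``max_overlap`` down to ``min_overlap`` and the longest one whose Hamming
mismatch fraction is within tolerance is reported.

The naive scan is O(max_overlap^2); here the per-length match counts are
computed exactly for all candidate lengths at once with an FFT
cross-correlation of one-hot base tracks, then each candidate within (or
bordering) tolerance is re-verified with an exact byte comparison, so float
rounding in the FFT cannot change a call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

DNA_BASES = b"ACGT"


@dataclass(frozen=True)
class OverlapResult:
    is_circular: bool
    overlap_len: int
    mismatch_frac: float | None
    trimmed_length: int | None


def detect_terminal_overlap(
    seq: str,
    min_overlap: int = 1000,
    max_overlap: int = 50_000,
    max_mismatch_frac: float = 0.02,
) -> OverlapResult:
    """Find the longest prefix/suffix overlap within a mismatch tolerance.

    Substitution-only (Hamming) comparison at each candidate overlap length;
    the sequence must be longer than ``2 * min_overlap``.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    n = len(seq)
    if n <= 2 * min_overlap:
        raise ValueError(
            f"sequence length {n} too short for terminal-overlap scan "
            f"(needs > {2 * min_overlap})"
        )
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    k = min(max_overlap, n - 1)
    prefix = arr[:k].astype(np.float64)
    suffix = arr[n - k :].astype(np.float64)

    # matches(L) for all L in [1, k]: correlate one-hot tracks of the prefix
    # window with the suffix window; overlap L corresponds to shift k - L.
    corr = np.zeros(2 * k - 1)
    pre_u8 = arr[:k]
    suf_u8 = arr[n - k :]
    for base in DNA_BASES:
        a = (pre_u8 == base).astype(np.float64)
        b = (suf_u8 == base).astype(np.float64)
        corr += fftconvolve(b, a[::-1])
    lengths = np.arange(k, 0, -1)  # L at shift t = k - L, t = 0..k-1
    match_est = np.rint(corr[k - 1 :]).astype(np.int64)
    mismatch_est = lengths - match_est

    # one mismatch of slack absorbs any FFT rounding; candidates are verified.
    allowed = np.floor(max_mismatch_frac * lengths).astype(np.int64) + 1
    cand = lengths[(lengths >= min_overlap) & (mismatch_est <= allowed)]
    for L in cand:  # descending: longest overlap wins
        L = int(L)
        mm = int(np.count_nonzero(arr[:L] != arr[n - L :]))
        if mm <= max_mismatch_frac * L:
            return OverlapResult(
                is_circular=True,
                overlap_len=L,
                mismatch_frac=mm / L,
                trimmed_length=n - L,
            )
    return OverlapResult(is_circular=False, overlap_len=0, mismatch_frac=None, trimmed_length=None)


def circularize(seq: str, result: OverlapResult) -> str:
    """Trim the duplicated terminal overlap off a circular contig.

    The rotation start is unchanged; only the trailing copy of the overlap is
    removed. Calling this with a linear ``OverlapResult`` is an error.
    """
    if not result.is_circular or result.overlap_len <= 0:
        raise ValueError("circularize requires a circular OverlapResult with overlap_len > 0")
    return seq[: len(seq) - result.overlap_len]
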