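"""Deterministic pairwise overlap alignment for 16S identity arithmetic.

Full-length 16S comparisons here need two things a generic aligner does not
promise: (i) terminal gaps on *either* sequence are free, so a gene hanging
over the end of a shorter reference (or vice versa) is not penalised and the
query-coverage filter is meaningful in both directions, and (ii) the alignment
returned for a given input pair is a pinned, reproducible choice among
co-optimal alignments, so the identity value is a well-defined function of the
two sequences rather than of a library's internal tie-breaking.

The definition used throughout the package:

* scoring: match +1, mismatch -1, gap -5 (linear gap cost; the strong gap
  penalty suits substitution-dominated comparisons of full-length consensus
  sequences and keeps identity arithmetic faithful to planted divergence);
* overlap mode: leading and trailing unaligned stretches of either sequence
  cost nothing;
* endpoint: highest-scoring cell on the last row/column of the DP matrix,
  ties resolved toward larger query index, then larger reference index;
* traceback: diagonal preferred over up (query gap consumed) over left;
* identity = matches / aligned core columns x 100, where the core is the
  traceback path (internal gaps count as columns, terminal free gaps do not);
* query coverage = query bases inside the core / query length x 100.

The matrix fill is numba-compiled; the traceback is O(m+n) Python.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

MATCH = 1
MISMATCH = -1
GAP = -5


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of one overlap alignment (percent scales, 0-based half-open spans)."""

    score: int
    identity: float
    query_coverage: float
    matches: int
    columns: int
    query_span: tuple[int, int]
    ref_span: tuple[int, int]


@njit(cache=True)
def _fill_matrix(q, r, match, mismatch, gap):  # pragma: no cover - exercised via align_overlap
    m = q.size
    n = r.size
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            s = match if qi == r[j - 1] else mismatch
            best = H[i - 1, j - 1] + s
            up = H[i - 1, j] + gap
            if up > best:
                best = up
            left = H[i, j - 1] + gap
            if left > best:
                best = left
            H[i, j] = best
    return H


def _to_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _endpoint(H: np.ndarray, m: int, n: int) -> tuple[int, int]:
    """Best cell on the last row or column; ties -> larger i, then larger j."""
    last_col = H[:, n]
    last_row = H[m, :]
    best = int(max(last_col.max(), last_row.max()))
    ci = np.flatnonzero(last_col == best)
    cj = np.flatnonzero(last_row == best)
    cand_i = (int(ci[-1]), n) if ci.size else None
    cand_j = (m, int(cj[-1])) if cj.size else None
    cands = [c for c in (cand_i, cand_j) if c is not None]
    return max(cands)


def align_overlap(
    query: str,
    ref: str,
    match: int = MATCH,
    mismatch: int = MISMATCH,
    gap: int = GAP,
) -> AlignmentResult:
    """Align ``query`` against ``ref`` in overlap mode and score the core.

    Raises ``ValueError`` on empty input. See the module docstring for the
    exact alignment definition (scoring, tie-breaks, identity/coverage).
    """
    if not query or not ref:
        raise ValueError("align_overlap requires two non-empty sequences")
    q = _to_bytes(query)
    r = _to_bytes(ref)
    H = _fill_matrix(q, r, match, mismatch, gap)
    m, n = q.size, r.size
    ei, ej = _endpoint(H, m, n)
    i, j = ei, ej
    matches = 0
    columns = 0
    while i > 0 and j > 0:
        s = match if q[i - 1] == r[j - 1] else mismatch
        h = H[i, j]
        if h == H[i - 1, j - 1] + s:
            if q[i - 1] == r[j - 1]:
                matches += 1
            i -= 1
            j -= 1
        elif h == H[i - 1, j] + gap:
            i -= 1
        else:
            j -= 1
        columns += 1
    identity = 100.0 * matches / columns if columns else 0.0
    coverage = 100.0 * (ei - i) / m
    return AlignmentResult(
        score=int(H[ei, ej]),
        identity=identity,
        query_coverage=coverage,
        matches=matches,
        columns=columns,
        query_span=(i, ei),
        ref_span=(j, ej),
    )


def pairwise_identity(query: str, ref: str) -> tuple[float, float]:
    """Percent identity and percent query coverage of the overlap alignment."""
    res = align_overlap(query, ref)
    return res.identity, res.query_coverage
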