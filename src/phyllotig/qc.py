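"""Assembly-level quality control: summary statistics and contig filters.

Mirrors the post-assembly bookkeeping of a long-read metagenome study: an
assembly summary table (contig counts, total bases, N50, large/circular contig
counts), a read-depth filter that keeps "high quality" contigs, and a screen
for artificial contigs made of long single-nucleotide stretches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.SeqUtils import gc_fraction


class MissingDepthError(KeyError):
    """A contig has no entry in the depth table."""

    def __init__(self, contig_id: str):
        super().__init__(contig_id)
        self.contig_id = contig_id

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return f"no depth entry for contig {self.contig_id!r}"


@dataclass
class Contig:
    """An assembled contig with lazily-joined depth and circularity."""

    contig_id: str
    sequence: str
    mean_depth: float | None = None
    circular: bool | None = None
    length: int = field(init=False)
    gc: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"contig {self.contig_id!r} has an empty sequence")
        self.length = len(self.sequence)
        self.gc = 100.0 * gc_fraction(self.sequence)


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    total_bp: int
    bp_ge_50kbp: int
    largest_bp: int
    n50: int
    n_ge_1mbp: int
    n_circular: int | None
    n_cds: int | None = None


def compute_n50(lengths: Sequence[int]) -> int:
    """N50: the length L at which the largest-first cumulative sum first
    reaches half of the total bases (contigs of length >= L hold >= half)."""
    if not lengths:
        raise ValueError("compute_n50 requires at least one length")
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    half = arr.sum() / 2.0
    cum = np.cumsum(arr)
    return int(arr[np.argmax(cum >= half)])


def compute_stats(contigs: Iterable[Contig], n_cds: int | None = None) -> AssemblyStats:
    """Assembly summary over a contig set; permutation-invariant.

    ``n_circular`` is populated only when every contig has its circularity
    flag set (the count is meaningless on a partially-annotated set) and
    ``n_cds`` is pass-through from upstream gene calling.
    """
    contigs = list(contigs)
    if not contigs:
        raise ValueError("compute_stats requires a non-empty contig set")
    lengths = [c.length for c in contigs]
    flags = [c.circular for c in contigs]
    n_circ = sum(bool(f) for f in flags) if all(f is not None for f in flags) else None
    return AssemblyStats(
        n_contigs=len(contigs),
        total_bp=int(sum(lengths)),
        bp_ge_50kbp=int(sum(l for l in lengths if l >= 50_000)),
        largest_bp=int(max(lengths)),
        n50=compute_n50(lengths),
        n_ge_1mbp=sum(l >= 1_000_000 for l in lengths),
        n_circular=n_circ,
        n_cds=n_cds,
    )


def filter_high_quality(
    contigs: Iterable[Contig],
    depths: Mapping[str, float],
    min_depth: float = 5.0,
) -> list[Contig]:
    """Keep contigs with mean depth strictly greater than ``min_depth``.

    Order-preserving; every input contig must appear in ``depths`` (the joined
    depth is written onto the returned contigs). The strict ``>`` follows the
    high-quality filter wording; 16S eligibility elsewhere uses ``>=``.
    """
    kept: list[Contig] = []
    for contig in contigs:
        if contig.contig_id not in depths:
            raise MissingDepthError(contig.contig_id)
        depth = float(depths[contig.contig_id])
        contig.mean_depth = depth
        if depth > min_depth:
            kept.append(contig)
    return kept


def detect_low_complexity(
    contig: Contig | str,
    max_mono_run_frac: float = 0.5,
    min_run: int = 1000,
) -> bool:
    """Flag artificial contigs dominated by a single nucleotide.

    True iff the sequence contains a single-base run of at least ``min_run``
    bases, or any one base makes up more than ``max_mono_run_frac`` of it.
    """
    seq = contig.sequence if isinstance(contig, Contig) else contig
    if not seq:
        raise ValueError("detect_low_complexity requires a non-empty sequence")
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    counts = np.bincount(arr, minlength=256)
    if counts.max() / arr.size > max_mono_run_frac:
        return True
    # longest homopolymer run via change-point positions
    breaks = np.flatnonzero(np.diff(arr) != 0)
    edges = np.concatenate(([-1], breaks, [arr.size - 1]))
    longest = int(np.diff(edges).max())
    return longest >= min_run
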