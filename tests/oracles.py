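"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is written against the documented definition of its operation,
deliberately sharing no code with the package: scalar dynamic programming for
alignment, naive descending scans for terminal overlaps, all-pairs matrices
for clustering, and plain summations for profiles.
"""

from __future__ import annotations

def oracle_align(query: str, ref: str, match: int = 1, mismatch: int = -1, gap: int = -5):
    """Scalar overlap-alignment DP with the package's documented tie-breaks.

    Returns (score, identity_percent, query_coverage_percent).
    """
    m, n = len(query), len(ref)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        qi = query[i - 1]
        row = H[i]
        prev = H[i - 1]
        for j in range(1, n + 1):
            s = match if qi == ref[j - 1] else mismatch
            row[j] = max(prev[j - 1] + s, prev[j] + gap, row[j - 1] + gap)
    # endpoint on last row/column: max score, ties toward larger i then larger j
    best_i = max(range(m + 1), key=lambda i: (H[i][n], i))
    best_j = max(range(n + 1), key=lambda j: (H[m][j], j))
    ei, ej = max([(best_i, n), (m, best_j)], key=lambda c: (H[c[0]][c[1]], c[0], c[1]))
    score = H[ei][ej]
    i, j = ei, ej
    matches = columns = 0
    while i > 0 and j > 0:
        s = match if query[i - 1] == ref[j - 1] else mismatch
        if H[i][j] == H[i - 1][j - 1] + s:
            matches += query[i - 1] == ref[j - 1]
            i, j = i - 1, j - 1
        elif H[i][j] == H[i - 1][j] + gap:
            i -= 1
        else:
            j -= 1
        columns += 1
    identity = 100.0 * matches / columns if columns else 0.0
    coverage = 100.0 * (ei - i) / m
    return score, identity, coverage


def oracle_n50(lengths) -> int:
    """Brute-force N50: scan candidate cut lengths largest-first."""
    total = sum(lengths)
    for cut in sorted(set(lengths), reverse=True):
        if sum(l for l in lengths if l >= cut) * 2 >= total:
            return cut
    raise AssertionError("unreachable for non-empty input")


def oracle_terminal_overlap(seq: str, min_overlap: int, max_overlap: int, max_mismatch_frac: float):
    """Naive Hamming scan over all candidate overlap lengths, longest first.

    Returns (overlap_len, mismatch_frac) or None.
    """
    n = len(seq)
    for L in range(min(max_overlap, n - 1), min_overlap - 1, -1):
        mm = sum(a != b for a, b in zip(seq[:L], seq[n - L :]))
        if mm <= max_mismatch_frac * L:
            return L, mm / L
    return None


def oracle_greedy_cluster(records, min_len: int, threshold: float, identity_fn, min_coverage: float = 90.0):
    """Greedy clustering driven by a precomputed all-pairs identity matrix.

    ``identity_fn`` returns (identity, query_coverage); a record is absorbed
    only when identity >= threshold over an alignment covering at least
    ``min_coverage`` percent of it.
    """
    survivors = sorted((r for r in records if r.length > min_len), key=lambda r: (-r.length, r.ref_id))
    ident = {}
    for a in survivors:
        for b in survivors:
            if a.ref_id != b.ref_id and (a.ref_id, b.ref_id) not in ident:
                identity, coverage = identity_fn(a.sequence, b.sequence)
                ident[(a.ref_id, b.ref_id)] = identity if coverage >= min_coverage else 0.0
    reps = []
    for rec in survivors:
        if not any(ident[(rec.ref_id, rep.ref_id)] >= threshold for rep in reps):
            reps.append(rec)
    return reps


def oracle_profile(assignments, genes, weighting: str) -> dict[str, float]:
    """Plain-summation depth-weighted species profile (percent)."""
    gene_by_id = {g.gene_id: g for g in genes}
    weights: dict[str, float] = {}
    seen_contigs: set[tuple[str, str]] = set()
    for a in assignments:
        if a.novelty_flag != "known_species":
            continue
        g = gene_by_id[a.gene_id]
        taxon = a.lineage[-1]
        if weighting == "per_contig":
            if (taxon, g.contig_id) in seen_contigs:
                continue
            seen_contigs.add((taxon, g.contig_id))
        weights[taxon] = weights.get(taxon, 0.0) + g.contig_depth
    total = sum(weights.values())
    return {t: 100.0 * w / total for t, w in weights.items()}


def oracle_rotated_subsequence(observed, reference) -> bool:
    """Brute-force rotation/strand scan for the de-duplicated observed order."""
    dedup = list(dict.fromkeys(observed))
    if not dedup:
        return True

    def is_subseq(small, big):
        pos = 0
        for x in big:
            if pos < len(small) and small[pos] == x:
                pos += 1
        return pos == len(small)

    for variant in (list(reference), list(reference)[::-1]):
        for shift in range(len(variant)):
            if is_subseq(dedup, variant[shift:] + variant[:shift]):
                return True
    return False


def random_dna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT")) for _ in range(length))


def mutate_with_indels(rng, seq: str, sub_rate: float, indel_rate: float) -> str:
    out = []
    bases = "ACGT"
    for ch in seq:
        r = rng.random()
        if r < indel_rate / 2:
            continue  # deletion
        if r < indel_rate:
            out.append(rng.choice(bases))  # insertion before the base
        if rng.random() < sub_rate:
            ch = rng.choice([b for b in bases if b != ch])
        out.append(ch)
    return "".join(out) or "A"
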