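"""Independent oracles used by the test suite.

The alignment oracle is a Waterman-Smith-Beyer style DP: gaps are scored
by explicit length enumeration (``cost(L) = gap_open + L * gap_extend``)
instead of the three-state affine recurrence used by the implementation,
so the two routes share no code or algorithmic shortcut.
"""

from __future__ import annotations

import numpy as np

NEG = -1e30


def wsb_align_score(query: str, target: str, match: float = 5.0,
                    mismatch: float = -4.0, gap_open: float = 10.0,
                    gap_extend: float = 0.5,
                    free_end_gaps: bool = True) -> float:
    """Full-matrix gap-length-enumeration DP; score only."""
    n, m = len(query), len(target)
    best = np.full((n + 1, m + 1), NEG)
    best[0, 0] = 0.0
    if free_end_gaps:
        best[1:, 0] = 0.0
        best[0, 1:] = 0.0
    else:
        best[1:, 0] = -(gap_open + gap_extend * np.arange(1, n + 1))
        best[0, 1:] = -(gap_open + gap_extend * np.arange(1, m + 1))
    for i in range(1, n + 1):
        qc = query[i - 1]
        for j in range(1, m + 1):
            s = match if (qc == "N" or qc == target[j - 1]) else mismatch
            diag = best[i - 1, j - 1] + s
            ks = np.arange(1, i + 1)
            up = np.max(best[i - ks, j] - (gap_open + gap_extend * ks))
            ks = np.arange(1, j + 1)
            left = np.max(best[i, j - ks] - (gap_open + gap_extend * ks))
            best[i, j] = max(diag, up, left)
    if free_end_gaps:
        return float(max(best[n, :].max(), best[:, m].max()))
    return float(best[n, m])


def binom_two_sided_minlike(k: int, n: int, p: float) -> float:
    """Two-sided exact binomial p-value by direct PMF summation: the sum of
    all outcome probabilities not exceeding the observed one."""
    from scipy.stats import binom

    pmf = binom.pmf(np.arange(n + 1), n, p)
    observed = pmf[k]
    return float(pmf[pmf <= observed * (1 + 1e-10)].sum())


def recount_end_profile(reads):
    """Brute-force recount of read start/end positions."""
    starts: dict[int, int] = {}
    ends: dict[int, int] = {}
    for r in reads:
        starts[r.ref_start] = starts.get(r.ref_start, 0) + 1
        ends[r.ref_end] = ends.get(r.ref_end, 0) + 1
    return starts, ends


def brute_force_candidates(reads, min_support, flank, p_threshold,
                           lambda_floor, length):
    """O(L*N) scan over every position of a small contig."""
    from scipy.stats import poisson

    combined = np.zeros(length + 1, dtype=np.int64)
    for r in reads:
        combined[r.ref_start] += 1
        combined[r.ref_end] += 1
    out = []
    for pos in range(length + 1):
        c = int(combined[pos])
        if c < min_support:
            continue
        lo, hi = max(0, pos - flank), min(length, pos + flank)
        local = int(combined[lo:hi + 1].sum()) - c
        lam = max(lambda_floor, local / (2.0 * flank))
        p = float(poisson.sf(c - 1, lam))
        if p < p_threshold:
            out.append((pos, c, lam, p))
    return out


def recount_indel_starts(reads, contig, start, end):
    """Per-position exhaustive recount of covering reads and indel starts."""
    width = end - start
    cov = np.zeros(width, dtype=np.int64)
    ins = np.zeros(width, dtype=np.int64)
    dele = np.zeros(width, dtype=np.int64)
    for r in reads:
        if r.contig != contig:
            continue
        for p in range(max(r.ref_start, start), min(r.ref_end, end)):
            cov[p - start] += 1
        for pos, kind, _ in r.cigar_indels:
            if start <= pos < end and r.ref_start <= pos < r.ref_end:
                (ins if kind == "ins" else dele)[pos - start] += 1
    return cov, ins, dele
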