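"""Global alignment of guide queries against reference windows.

Needleman-Wunsch with affine gap penalties and free end gaps, using the
EMBOSS-Needle DNA defaults: match +5, mismatch -4, gap open 10.0, gap
extend 0.5, terminal gaps unpenalized.  A gap of length L costs
``gap_open + L * gap_extend`` (the opening move costs 10.5, each further
extension 0.5).  ``N`` in the query is a +5 wildcard against any target
base (it carries the PAM's N); ``N`` in the target scores as a mismatch
unless matched by a query ``N``.

Among co-optimal alignments the traceback deterministically prefers
diagonal moves, then gaps in the target, then gaps in the query.  The
tested contract is the score; the path preference is a documented
convention.
"""

from __future__ import annotations

from dataclasses import dataclass

NEG_INF = float("-inf")


@dataclass(frozen=True)
class ScoringScheme:
    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 10.0
    gap_extend: float = 0.5
    free_end_gaps: bool = True

    def substitution(self, q: str, t: str) -> float:
        if q == "N" or q == t:
            return self.match
        return self.mismatch


DEFAULT_SCORING = ScoringScheme()

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _validate(seq: str, what: str) -> None:
    if not seq:
        raise ValueError(f"{what} sequence is empty")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"{what} contains non-ACGTN characters: {sorted(bad)}")


def global_align(query: str, target: str,
                 scoring: ScoringScheme = DEFAULT_SCORING
                 ) -> tuple[float, str, str]:
    """Align ``query`` against ``target`` globally with free end gaps.

    Returns ``(score, aligned_query, aligned_target)`` where the gapped
    strings have equal length and cover both sequences end to end
    (terminal gaps included).
    """
    _validate(query, "query")
    _validate(target, "target")
    n, m = len(query), len(target)
    open_cost = scoring.gap_open + scoring.gap_extend
    ext = scoring.gap_extend
    free = scoring.free_end_gaps

    # M: q[i-1] aligned to t[j-1]; X: gap in target (query char vs '-');
    # Y: gap in query ('-' vs target char).
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = 0.0 if free else -(scoring.gap_open + i * ext)
    for j in range(1, m + 1):
        Y[0][j] = 0.0 if free else -(scoring.gap_open + j * ext)

    for i in range(1, n + 1):
        qc = query[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, m + 1):
            s = scoring.substitution(qc, target[j - 1])
            Mi[j] = s + max(Mp[j - 1], Xp[j - 1], Yp[j - 1])
            X_open = max(Mp[j], Yp[j]) - open_cost
            Xi[j] = max(X_open, Xp[j] - ext)
            Y_open = max(Mi[j - 1], Xi[j - 1]) - open_cost
            Yi[j] = max(Y_open, Yi[j - 1] - ext)

    def best(i: int, j: int) -> float:
        return max(M[i][j], X[i][j], Y[i][j])

    if free:
        # Trailing gaps are free: finish anywhere on the last row/column.
        end_i, end_j, score = n, m, best(n, m)
        for i in range(n - 1, -1, -1):
            if best(i, m) > score:
                end_i, end_j, score = i, m, best(i, m)
        for j in range(m - 1, -1, -1):
            if best(n, j) > score:
                end_i, end_j, score = n, j, best(n, j)
    else:
        end_i, end_j, score = n, m, best(n, m)

    aq: list[str] = []
    at: list[str] = []
    # Trailing free gaps from (end_i, end_j) to the corner.
    for i in range(n, end_i, -1):
        aq.append(query[i - 1]); at.append("-")
    for j in range(m, end_j, -1):
        aq.append("-"); at.append(target[j - 1])

    i, j = end_i, end_j
    # Current matrix: prefer M, then X, then Y.
    val = best(i, j)
    if M[i][j] == val:
        state = "M"
    elif X[i][j] == val:
        state = "X"
    else:
        state = "Y"
    while i > 0 or j > 0:
        if i == 0:
            aq.append("-"); at.append(target[j - 1]); j -= 1
            continue
        if j == 0:
            aq.append(query[i - 1]); at.append("-"); i -= 1
            continue
        if state == "M":
            aq.append(query[i - 1]); at.append(target[j - 1])
            prev = M[i][j] - scoring.substitution(query[i - 1], target[j - 1])
            i -= 1; j -= 1
            if M[i][j] == prev:
                state = "M"
            elif X[i][j] == prev:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            aq.append(query[i - 1]); at.append("-")
            here = X[i][j]
            i -= 1
            if M[i][j] - open_cost == here:
                state = "M"
            elif X[i][j] - ext == here:
                state = "X"
            else:
                state = "Y"
        else:  # Y
            aq.append("-"); at.append(target[j - 1])
            here = Y[i][j]
            j -= 1
            if M[i][j] - open_cost == here:
                state = "M"
            elif X[i][j] - open_cost == here:
                state = "X"
            else:
                state = "Y"
    aq.reverse()
    at.reverse()
    return score, "".join(aq), "".join(at)


def alignment_score_of(aligned_query: str, aligned_target: str,
                       scoring: ScoringScheme = DEFAULT_SCORING) -> float:
    """Score a gapped alignment column by column (consistency checks)."""
    if len(aligned_query) != len(aligned_target):
        raise ValueError("gapped strings differ in length")
    score = 0.0
    n_cols = len(aligned_query)
    in_gap = None  # 'q' or 't'
    for k, (q, t) in enumerate(zip(aligned_query, aligned_target)):
        if q == "-" and t == "-":
            raise ValueError("double-gap column")
        if q == "-" or t == "-":
            side = "q" if q == "-" else "t"
            terminal = False
            if scoring.free_end_gaps:
                # terminal iff the gapped side has no residue before or after
                gapped = aligned_query if side == "q" else aligned_target
                terminal = (all(c == "-" for c in gapped[:k])
                            or all(c == "-" for c in gapped[k + 1:]))
            if terminal:
                in_gap = None
            else:
                if in_gap == side:
                    score -= scoring.gap_extend
                else:
                    score -= scoring.gap_open + scoring.gap_extend
                in_gap = side
            continue
        in_gap = None
        score += scoring.substitution(q, t)
    return score
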