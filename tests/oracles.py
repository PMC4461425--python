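"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately written from the definitions, without
reusing any package internals beyond plain data types.
"""

from __future__ import annotations

import itertools

from otubench.pairwise_identity import ScoringScheme


def score_gapped_pair(gapped_a: str, gapped_b: str,
                      scoring: ScoringScheme) -> float:
    """Score an explicit alignment from first principles.

    Match/mismatch per non-gap column ('N' scores 0 as a wildcard); each
    maximal gap run costs open + (k-1)*extend, with the end-gap rates for
    runs touching the first or last column.
    """
    length = len(gapped_a)
    total = 0.0
    for ca, cb in zip(gapped_a, gapped_b):
        if ca == "-" or cb == "-":
            continue
        if ca == "N" or cb == "N":
            total += 0.0
        elif ca == cb:
            total += scoring.match
        else:
            total += scoring.mismatch
    for row in (gapped_a, gapped_b):
        i = 0
        while i < length:
            if row[i] == "-":
                j = i
                while j < length and row[j] == "-":
                    j += 1
                k = j - i
                if i == 0 or j == length:
                    total += scoring.end_gap_open + (k - 1) * scoring.end_gap_extend
                else:
                    total += scoring.gap_open + (k - 1) * scoring.gap_extend
                i = j
            else:
                i += 1
    return total


def all_alignments(a: str, b: str):
    """Exhaustively enumerate every global alignment of a and b."""
    if not a and not b:
        yield ("", "")
        return
    if a:
        for ga, gb in all_alignments(a[1:], b):
            yield (a[0] + ga, "-" + gb)
    if b:
        for ga, gb in all_alignments(a, b[1:]):
            yield ("-" + ga, b[0] + gb)
    if a and b:
        for ga, gb in all_alignments(a[1:], b[1:]):
            yield (a[0] + ga, b[0] + gb)


def oracle_best_score(a: str, b: str, scoring: ScoringScheme) -> float:
    """Optimal alignment score by exhaustive enumeration (tiny inputs)."""
    return max(score_gapped_pair(ga, gb, scoring)
               for ga, gb in all_alignments(a, b))


def oracle_identity(gapped_a: str, gapped_b: str, definition: str,
                    terminal_policy: str) -> float:
    """Identity computed directly from the verbal definitions."""
    length = len(gapped_a)
    m = x = 0
    runs = []  # (k, is_terminal)
    for ca, cb in zip(gapped_a, gapped_b):
        if ca == "-" or cb == "-":
            continue
        if ca == cb or "N" in (ca, cb):
            m += 1
        else:
            x += 1
    for row in (gapped_a, gapped_b):
        i = 0
        while i < length:
            if row[i] == "-":
                j = i
                while j < length and row[j] == "-":
                    j += 1
                runs.append((j - i, i == 0 or j == length))
                i = j
            else:
                i += 1
    if definition == "no_gaps":
        denom = m + x
    elif definition == "one_gap":
        denom = m + x + sum(1 for _, term in runs
                            if not term or terminal_policy == "count")
    else:
        denom = m + x + sum(k for k, term in runs
                            if not term or terminal_policy == "count")
    return m / denom


def gotoh_best_score(a: str, b: str, scoring: ScoringScheme) -> float:
    """Independent affine-gap DP with separate terminal-gap rates.

    Three-state Gotoh recurrence; leading gap runs are charged end rates
    via the initialisation, trailing runs via the final maximisation
    (only from states whose last column is not a gap in the same
    sequence, so maximal terminal runs are charged uniformly).
    """
    n, m = len(a), len(b)
    NEG = float("-inf")

    def sub(ca, cb):
        if ca == "N" or cb == "N":
            return 0.0
        return scoring.match if ca == cb else scoring.mismatch

    def end_run(k):
        return 0.0 if k == 0 else scoring.end_gap_open + (k - 1) * scoring.end_gap_extend

    M = [[NEG] * (m + 1) for _ in range(n + 1)]   # last column: diagonal
    Ga = [[NEG] * (m + 1) for _ in range(n + 1)]  # last column: gap in b
    Gb = [[NEG] * (m + 1) for _ in range(n + 1)]  # last column: gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ga[i][0] = end_run(i)
    for j in range(1, m + 1):
        Gb[0][j] = end_run(j)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub(a[i - 1], b[j - 1])
            M[i][j] = max(M[i - 1][j - 1], Ga[i - 1][j - 1],
                          Gb[i - 1][j - 1]) + s
            Ga[i][j] = max(M[i - 1][j] + scoring.gap_open,
                           Gb[i - 1][j] + scoring.gap_open,
                           Ga[i - 1][j] + scoring.gap_extend)
            Gb[i][j] = max(M[i][j - 1] + scoring.gap_open,
                           Ga[i][j - 1] + scoring.gap_open,
                           Gb[i][j - 1] + scoring.gap_extend)
    best = NEG
    for i in range(n + 1):
        # consume a[i:] as a trailing terminal run (gap in b); the run must
        # not extend a gap-in-b column, so exclude state Ga unless i == n
        for state in (M, Gb):
            if state[i][m] > NEG:
                best = max(best, state[i][m] + end_run(n - i))
        if i == n and Ga[n][m] > NEG:
            best = max(best, Ga[n][m])
    for j in range(m + 1):
        for state in (M, Ga):
            if state[n][j] > NEG:
                best = max(best, state[n][j] + end_run(m - j))
        if j == m and Gb[n][m] > NEG:
            best = max(best, Gb[n][m])
    return best


def naive_agglomerate(dmat, linkage: str, cutoff: float) -> set[frozenset]:
    """O(n^3) agglomeration straight from the linkage definitions."""
    n = len(dmat)
    clusters: list[set[int]] = [{i} for i in range(n)]

    def linkdist(ca: set[int], cb: set[int]) -> float:
        pairs = [dmat[i][j] for i in ca for j in cb]
        if linkage == "average":
            return sum(pairs) / len(pairs)
        if linkage == "furthest":
            return max(pairs)
        return min(pairs)

    while len(clusters) > 1:
        best = None
        for p, q in itertools.combinations(range(len(clusters)), 2):
            d = linkdist(clusters[p], clusters[q])
            key = (d, min(clusters[p]), min(clusters[q]))
            if best is None or key < best[0]:
                best = (key, p, q)
        (d, _, _), p, q = best
        if d > cutoff:
            break
        clusters[p] = clusters[p] | clusters[q]
        del clusters[q]
    return {frozenset(c) for c in clusters}
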