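"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's fast-path implementations: the MH
oracle enumerates deletion placements by string equality, the alignment oracle
is a standalone Gotoh DP, and the motif oracle is a naive O(n*m) scan.
"""

from __future__ import annotations

import itertools
import math

_COMP = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def mh_by_enumeration(seq: str, start: int, end: int) -> int:
    """Placement count minus one, by exhaustive string comparison."""
    L = end - start + 1
    repaired = seq[: start - 1] + seq[end:]
    count = 0
    for s in range(1, len(seq) - L + 2):
        if seq[: s - 1] + seq[s - 1 + L :] == repaired:
            count += 1
    return count - 1


def naive_motif_scan(seq: str, motif: str) -> list[tuple[int, str]]:
    """All (1-based start, strand) occurrences by direct comparison."""
    hits = []
    probes = [("+", motif)]
    if rc(motif) != motif:
        probes.append(("-", rc(motif)))
    for strand, probe in probes:
        for i in range(len(seq) - len(probe) + 1):
            if all(seq[i + j] == probe[j] for j in range(len(probe))):
                hits.append((i + 1, strand))
    return sorted(hits)


def gotoh_score(
    ref: str, read: str, match=2, mismatch=-4, gap_open=-6, gap_extend=-1
) -> float:
    """Global affine-gap alignment score; gap of length g costs
    -(gap_open + (g-1)*gap_extend)."""
    n, m = len(ref), len(read)
    NEG = -math.inf
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in read (deletion)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in ref (insertion)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if ref[i - 1] == read[j - 1] else mismatch
            best_prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = best_prev + s
            X[i][j] = max(
                M[i - 1][j] + gap_open,
                X[i - 1][j] + gap_extend,
                Y[i - 1][j] + gap_open,
            )
            Y[i][j] = max(
                M[i][j - 1] + gap_open,
                Y[i][j - 1] + gap_extend,
                X[i][j - 1] + gap_open,
            )
    return max(M[n][m], X[n][m], Y[n][m])


def leftmost_deletion_placement(ref: str, read: str, length: int) -> tuple[int, int]:
    """Smallest-start (start, end) deletion of ``length`` turning ref into read.

    Exhaustive enumeration; raises if none exists.
    """
    for start in range(1, len(ref) - length + 2):
        if ref[: start - 1] + ref[start - 1 + length :] == read:
            return start, start + length - 1
    raise AssertionError("no single-deletion placement explains the read")


def leftmost_insertion_placement(ref: str, read: str, length: int) -> tuple[int, str]:
    """Smallest-position (pos, inserted_seq) turning ref into read."""
    for pos in range(0, len(ref) + 1):
        candidate = read[pos : pos + length]
        if ref[:pos] + candidate + ref[pos:] == read:
            return pos, candidate
    raise AssertionError("no single-insertion placement explains the read")


def exact_ranksum_p(a: list[float], b: list[float]) -> float:
    """Two-sided exact Mann-Whitney p by enumeration of group assignments."""
    pooled = sorted(a + b)
    ranks = {}
    # average ranks for ties
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and pooled[j] == pooled[i]:
            j += 1
        avg = (i + 1 + j) / 2.0
        ranks[pooled[i]] = avg
        i = j
    na = len(a)
    obs = sum(ranks[v] for v in a)
    values = [ranks[v] for v in pooled]
    total = 0
    as_extreme = 0
    mean = na * (len(pooled) + 1) / 2.0
    for combo in itertools.combinations(range(len(values)), na):
        s = sum(values[k] for k in combo)
        total += 1
        if abs(s - mean) >= abs(obs - mean) - 1e-12:
            as_extreme += 1
    return as_extreme / total


def poisson_tail(lam: float, c: int) -> float:
    """P(X >= c) for Poisson(lam) by direct summation."""
    p = math.exp(-lam)
    cdf = 0.0
    for k in range(0, c):
        cdf += p
        p *= lam / (k + 1)
    return 1.0 - cdf
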