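"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results with the simplest possible algorithm
(full dynamic programming, exhaustive pairing, O(n^2) scans, exhaustive
enumeration) and never call the implementation under test.
"""

from __future__ import annotations

import itertools

import numpy as np


def sw_score(target: str, query: str, matrix, gap_open: float,
             gap_extend: float) -> float:
    """Plain affine-gap local alignment best score (Gotoh, full matrices).

    A gap of length L costs ``gap_open + L * gap_extend``, matching the
    production aligner's convention.
    """
    n, m = len(target), len(query)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in query
    F = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in target
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] - gap_open - gap_extend,
                          E[i - 1][j] - gap_extend)
            F[i][j] = max(H[i][j - 1] - gap_open - gap_extend,
                          F[i][j - 1] - gap_extend)
            sub = matrix[target[i - 1], query[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def closure_partition(items, predicate) -> list[set[int]]:
    """Single-linkage transitive closure by exhaustive pairwise testing."""
    n = len(items)
    groups = [{i} for i in range(n)]
    changed = True
    while changed:
        changed = False
        for a, b in itertools.combinations(range(len(groups)), 2):
            if any(predicate(items[i], items[j])
                   for i in groups[a] for j in groups[b]):
                groups[a] |= groups[b]
                del groups[b]
                changed = True
                break
    return groups


def diagonal_repeat_windows(seq: str, length: int, min_identity: float,
                            d_min: int, d_max: int) -> list[tuple[int, int]]:
    """All (start, separation) windows of fixed ``length`` meeting identity.

    Exhaustive over every diagonal in the separation range, vectorised per
    diagonal.  Identity is the match fraction between ``seq[s:s+length]``
    and ``seq[s+d:s+d+length]``.
    """
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(arr)
    out = []
    need = min_identity / 100.0
    for d in range(d_min, min(d_max, n - length) + 1):
        matches = (arr[:n - d] == arr[d:])
        if len(matches) < length:
            continue
        cs = np.concatenate([[0], np.cumsum(matches)])
        window = cs[length:] - cs[:-length]   # sum over each length-window
        hits = np.flatnonzero(window / length >= need)
        out.extend((int(s), d) for s in hits)
    return out


def mannwhitney_enum_p(a, b) -> float:
    """Two-sided exact MWU p by enumerating every group-A index subset."""
    import scipy.stats as ss

    pooled = list(a) + list(b)
    ranks = ss.rankdata(pooled)
    n_a, n_b = len(a), len(b)
    mid = n_a * n_b / 2
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    dev = abs(u_obs - mid)
    hits = total = 0
    for combo in itertools.combinations(range(n_a + n_b), n_a):
        total += 1
        u = sum(ranks[i] for i in combo) - n_a * (n_a + 1) / 2
        if abs(u - mid) >= dev - 1e-9:
            hits += 1
    return hits / total


def wilcoxon_enum_p(diffs) -> float:
    """Two-sided exact signed-rank p over all 2^n sign assignments."""
    import scipy.stats as ss

    diffs = [d for d in diffs if d != 0]
    n = len(diffs)
    ranks = ss.rankdata([abs(d) for d in diffs])
    w_obs = sum(r for r, d in zip(ranks, diffs) if d > 0)
    mid = n * (n + 1) / 4
    dev = abs(w_obs - mid)
    hits = total = 0
    for signs in itertools.product((0, 1), repeat=n):
        total += 1
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mid) >= dev - 1e-9:
            hits += 1
    return hits / total
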