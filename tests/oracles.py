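"""Independent reference implementations used to verify the package.

These are deliberately written from first principles, in different form
from the library code: a memoized recursion over edit operations for
alignment scores, explicit pair counting for the adjusted Rand index,
and from-scratch cluster-distance recomputation for agglomerative
linkage.
"""

from __future__ import annotations

import itertools
from functools import lru_cache


def brute_force_nw_score(a: str, b: str, match: float, mismatch: float,
                         gap_open: float, gap_extend: float) -> float:
    """Best global affine-gap alignment score by memoized recursion.

    States track the previous operation so that a gap run of length k
    costs gap_open + (k - 1) * gap_extend.  Intended for short strings.
    """

    @lru_cache(maxsize=None)
    def best(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            options.append(s + best(i + 1, j + 1, "m"))
        if i < len(a):
            cost = gap_extend if prev == "a" else gap_open
            options.append(-cost + best(i + 1, j, "a"))
        if j < len(b):
            cost = gap_extend if prev == "b" else gap_open
            options.append(-cost + best(i, j + 1, "b"))
        return max(options)

    return best(0, 0, "m")


def pair_counting_ari(p: dict, q: dict) -> float:
    """Adjusted Rand index by explicit enumeration of item pairs."""
    ids = sorted(p)
    assert sorted(q) == ids
    n = len(ids)
    n11 = n00 = n10 = n01 = 0
    for x, y in itertools.combinations(ids, 2):
        same_p = p[x] == p[y]
        same_q = q[x] == q[y]
        if same_p and same_q:
            n11 += 1
        elif same_p:
            n10 += 1
        elif same_q:
            n01 += 1
        else:
            n00 += 1
    total = n * (n - 1) / 2
    a = n11 + n10  # pairs together in p
    b = n11 + n01  # pairs together in q
    expected = a * b / total
    max_index = (a + b) / 2
    if max_index == expected:
        # trivial complete agreement (every pair co-clustered in both) is
        # perfect; other degenerate cases score 0
        return 1.0 if n11 == total else 0.0
    return (n11 - expected) / (max_index - expected)


def naive_linkage(ids, d, method):
    """O(n^3) agglomerative clustering recomputing cluster distances from
    scratch at every step from the original matrix.

    ``d`` is a dict keyed by frozenset({id_i, id_j}).  Ties are broken by
    the sorted pair of smallest member ids.  Returns the merge history
    as (members_left, members_right, height) with members as sorted
    tuples.
    """
    clusters = [frozenset([i]) for i in ids]
    merges = []

    def cdist(c1, c2):
        vals = [d[frozenset([x, y])] for x in c1 for y in c2]
        if method == "complete":
            return max(vals)
        if method == "single":
            return min(vals)
        return sum(vals) / len(vals)

    while len(clusters) > 1:
        best = None
        for c1, c2 in itertools.combinations(clusters, 2):
            h = cdist(c1, c2)
            key = (h, tuple(sorted((min(c1), min(c2)))))
            if best is None or key < best[0]:
                best = (key, c1, c2)
        (h, _), c1, c2 = best
        merges.append((tuple(sorted(c1)), tuple(sorted(c2)), h))
        clusters = [c for c in clusters if c not in (c1, c2)] + [c1 | c2]
    return merges
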