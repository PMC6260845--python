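"""Independent brute-force oracles used by the tests.

These deliberately re-derive results by the most naive correct method
(double loops, exhaustive enumeration) and share no code with the package
paths they check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def naive_rollup(table, intensity_cols):
    """Per-protein, per-channel intensity sums by an explicit double loop."""
    out: dict[str, dict[str, float]] = {}
    for _, row in table.iterrows():
        acc = out.setdefault(row["protein_id"], {c: np.nan for c in intensity_cols})
        for c in intensity_cols:
            v = row[c]
            if np.isfinite(v):
                acc[c] = v if not np.isfinite(acc[c]) else acc[c] + v
    return out


def naive_channel_sums(table, intensity_cols):
    return {c: float(np.nansum(table[c].to_numpy(dtype=float))) for c in intensity_cols}


def naive_complete_linkage(points):
    """O(n^3) agglomeration with Euclidean complete linkage.

    Returns (heights, partitions) where ``heights`` is the list of merge
    heights in merge order and ``partitions[k]`` is the set-of-frozensets
    partition into k clusters (for k = n..1).
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    point_d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    clusters: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    heights = []
    partitions = {n: frozenset(clusters.values())}
    next_id = n
    for step in range(n - 1):
        best = None
        for a, b in combinations(sorted(clusters), 2):
            d = float(point_d[np.ix_(list(clusters[a]), list(clusters[b]))].max())
            if best is None or d < best[0] - 1e-15 or (abs(d - best[0]) <= 1e-15 and (a, b) < best[1:]):
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[next_id] = clusters.pop(a) | clusters.pop(b)
        next_id += 1
        partitions[n - step - 1] = frozenset(clusters.values())
    return heights, partitions


def exact_ranksum_two_sided(x, y):
    """Two-sided rank-sum p by exhaustive enumeration over rank assignments.

    Tie-free samples only.  p = 2 * min(P(W <= w), P(W >= w)) clipped at 1,
    where W is the rank sum of the first sample under the permutation null.
    """
    x = list(x)
    y = list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(rank[v] for v in x)
    n1 = len(x)
    le = ge = total = 0
    for subset in combinations(range(1, len(pooled) + 1), n1):
        w = sum(subset)
        total += 1
        le += w <= w_obs
        ge += w >= w_obs
    return min(1.0, 2.0 * min(le, ge) / total)


def naive_pair_tail_count(log2_ratios, mu, dev):
    """#{ordered pairs (i, j): |(x_i + x_j)/2 - mu| >= dev} by double loop."""
    xs = np.asarray(log2_ratios, dtype=float)
    count = 0
    for xi in xs:
        for xj in xs:
            if abs((xi + xj) / 2.0 - mu) >= dev:
                count += 1
    return count
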