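"""Hierarchical clustering of expression profiles and archetype classification.

Differential proteins are clustered on their log2 treatment/control summary
ratios over (Burned, Limit, Regular) with Euclidean distance and complete
(maximum) linkage, the dendrogram is cut into k flat clusters (default 14),
and every cluster centroid is classified by rule into one of four
archetypes:

1. Burned-high, Limit and Regular similar and lower;
2. Limit-high, Burned and Regular similar and lower;
3. monotone decreasing Burned > Limit > Regular, tracking the light dose;
4. everything else: flat profiles, or slightly Regular-leaning.

"High" means beyond ``tau`` (by default the log2 of the null model's upper
fold-change cutoff, so "high" = "beyond the significance cutoff") and
"similar" means within ``delta = tau/2``.  Classification is automatic for
every cluster -- no manual cluster picking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .design import TREATMENTS

__all__ = [
    "Dendrogram",
    "PatternAssignment",
    "DEFAULT_TAU",
    "build_matrix",
    "hclust_complete",
    "cut_clusters",
    "classify_pattern",
    "assign_patterns",
    "to_newick",
]

#: Fallback "high" threshold: log2 of the 1.61 fold-change scale.
DEFAULT_TAU = float(np.log2(1.61))


def build_matrix(calls: pd.DataFrame, enrichment: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Expression matrix of proteins significant in at least one condition.

    Rows are the union of the per-condition significant sets; columns are
    the log2 per-condition summary ratios (a protein significant only in
    Burned still contributes its Limit and Regular ratios).  Proteins with
    any missing condition are excluded and returned as the second element.
    """
    sig = sorted(set(calls.loc[calls["significant"], "protein_id"]))
    cols = [c.lower() for c in TREATMENTS]
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.log2(enrichment.loc[sig, cols].astype(float))
    mat.columns = list(TREATMENTS)
    complete = np.isfinite(mat.to_numpy()).all(axis=1)
    excluded = [pid for pid, ok in zip(mat.index, complete) if not ok]
    return mat.loc[complete], excluded


@dataclass
class Dendrogram:
    """Agglomeration result: scipy linkage matrix plus row labels.

    ``linkage`` rows are ``(member_a, member_b, height, size)`` with
    non-decreasing heights (guaranteed by complete linkage).
    """

    linkage: np.ndarray
    labels: list[str]

    @property
    def n(self) -> int:
        return len(self.labels)

    def merge_table(self) -> pd.DataFrame:
        t = pd.DataFrame(self.linkage, columns=["member_a", "member_b", "height", "size"])
        t[["member_a", "member_b", "size"]] = t[["member_a", "member_b", "size"]].astype(int)
        t.insert(0, "step", np.arange(1, len(t) + 1))
        return t


def hclust_complete(matrix: pd.DataFrame) -> Dendrogram:
    """Agglomerative clustering, Euclidean distance, complete linkage."""
    if len(matrix) < 2:
        raise ValueError("need at least 2 rows to cluster")
    Z = hierarchy.linkage(matrix.to_numpy(dtype=float), method="complete", metric="euclidean")
    return Dendrogram(Z, [str(i) for i in matrix.index])


def cut_clusters(dend: Dendrogram, k: int = 14) -> pd.Series:
    """Cut the dendrogram into exactly ``k`` flat clusters.

    The cut undoes the last ``k - 1`` merges.  Cluster ids are 1..k,
    ordered by size descending (ties broken by smallest member row, for
    determinism).
    """
    if not 1 <= k <= dend.n:
        raise ValueError(f"k must be in [1, {dend.n}], got {k}")
    raw = hierarchy.cut_tree(dend.linkage, n_clusters=k).ravel()
    order = sorted(
        np.unique(raw),
        key=lambda c: (-int((raw == c).sum()), int(np.argmax(raw == c))),
    )
    relabel = {c: i + 1 for i, c in enumerate(order)}
    return pd.Series([relabel[c] for c in raw], index=dend.labels, name="cluster")


def classify_pattern(centroid, tau: float = DEFAULT_TAU, delta: float | None = None) -> int:
    """Classify a (Burned, Limit, Regular) log2-ratio centroid into a pattern.

    Rule cascade, evaluated in the order 3, 1, 2, 4:

    * **3** if ``b > tau`` and ``b > l > r`` with ``b - r > delta`` and
      ``l - r >= (b - r) / 6`` -- a genuine graded decrease: the Limit
      value sits clearly above Regular on the Burned-to-Regular drop
      (a linear dose response puts it a third of the way up; a pure
      Burned spike puts it at zero; the boundary is halfway between);
    * **1** if ``b > tau``, ``b - max(l, r) > delta`` and ``|l - r|`` is
      small -- at most ``delta`` or half the drop from Burned, whichever
      is larger, so "Limit and Regular similar" is judged relative to how
      far below Burned they sit;
    * **2** if ``l > tau`` and ``l - max(b, r) > delta``;
    * **4** otherwise.
    """
    b, l, r = (float(x) for x in centroid)
    if not all(np.isfinite([b, l, r])):
        raise ValueError("centroid must be finite")
    if delta is None:
        delta = tau / 2.0
    if b > tau and b > l > r and (b - r) > delta and (l - r) >= (b - r) / 6.0:
        return 3
    if b > tau and (b - max(l, r)) > delta and abs(l - r) <= max(delta, (b - max(l, r)) / 2.0):
        return 1
    if l > tau and (l - max(b, r)) > delta:
        return 2
    return 4


@dataclass
class PatternAssignment:
    cluster_pattern: dict[int, int]  # cluster id -> pattern 1..4
    protein_cluster: pd.Series  # protein_id -> cluster id
    protein_pattern: pd.Series  # protein_id -> pattern
    centroids: pd.DataFrame  # cluster id x (Burned, Limit, Regular)

    @property
    def counts(self) -> dict[int, int]:
        c = self.protein_pattern.value_counts().to_dict()
        return {p: int(c.get(p, 0)) for p in (1, 2, 3, 4)}


def assign_patterns(
    clusters: pd.Series,
    matrix: pd.DataFrame,
    tau: float = DEFAULT_TAU,
    delta: float | None = None,
) -> PatternAssignment:
    """Assign each cluster (and so each protein) to a pattern archetype.

    The cluster centroid is the arithmetic column mean of its members'
    log2 ratios -- consistent with the Euclidean geometry of the
    clustering -- and is classified with :func:`classify_pattern`.
    """
    centroids = matrix.groupby(clusters).mean()
    centroids.index.name = "cluster"
    cluster_pattern = {
        int(cid): classify_pattern(row.to_numpy(), tau=tau, delta=delta)
        for cid, row in centroids.iterrows()
    }
    protein_pattern = clusters.map(cluster_pattern).rename("pattern")
    return PatternAssignment(cluster_pattern, clusters, protein_pattern, centroids)


def to_newick(dend: Dendrogram) -> str:
    """Serialize the dendrogram as a Newick string (branch lengths from heights)."""
    tree = hierarchy.to_tree(dend.linkage)
    # iterative post-order traversal; recursion would overflow on deep trees
    parts: dict[int, str] = {}
    height: dict[int, float] = {}
    stack = [(tree, False)]
    while stack:
        node, done = stack.pop()
        if node.is_leaf():
            parts[node.id] = dend.labels[node.id]
            height[node.id] = 0.0
            continue
        if not done:
            stack.append((node, True))
            stack.append((node.left, False))
            stack.append((node.right, False))
        else:
            lt = node.dist - height[node.left.id]
            rt = node.dist - height[node.right.id]
            parts[node.id] = (
                f"({parts[node.left.id]}:{lt:.6g},{parts[node.right.id]}:{rt:.6g})"
            )
            height[node.id] = node.dist
    return parts[tree.id] + ";"
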