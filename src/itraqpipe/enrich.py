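"""Expression-weighted category enrichment (Wilcoxon rank-sum, Bonferroni).

Rather than counting over-represented categories, each annotation category
is tested for a *shift* of its member proteins' log2 expression ratios
relative to all non-member proteins, so the expression ratios themselves
weight the category's representation.  The test is the two-sided Wilcoxon
rank-sum (Mann-Whitney) test with a reported shift direction; p-values are
Bonferroni-corrected over the categories tested within one condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["RankSumResult", "rank_sum_test", "enrich_categories"]

#: Largest combined sample for which the exact (enumeration) p-value is used.
EXACT_MAX_N = 25


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # Mann-Whitney U of the member sample
    p_two_sided: float
    direction: str  # "greater" | "smaller" | "undefined"


def rank_sum_test(values_in, values_out) -> RankSumResult:
    """Two-sided rank-sum test of member values against non-member values.

    Uses the exact null enumeration when ``n_in + n_out <= 25`` and there
    are no ties; otherwise the normal approximation with tie and continuity
    corrections.  ``direction`` is "greater" when the members' mean rank
    exceeds the non-members', "smaller" when below, and "undefined" when
    every value is identical (then p = 1).
    """
    x = np.asarray(values_in, dtype=float)
    y = np.asarray(values_out, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return RankSumResult(float(x.size * y.size / 2.0), 1.0, "undefined")
    ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= EXACT_MAX_N and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    ranks = stats.rankdata(combined)
    direction = "greater" if ranks[: x.size].mean() > ranks[x.size:].mean() else "smaller"
    return RankSumResult(float(res.statistic), float(res.pvalue), direction)


def enrich_categories(
    ratios: pd.Series,
    annotations: pd.DataFrame,
    condition: str = "",
    min_size: int = 5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test every annotation category for an expression shift in one condition.

    Parameters
    ----------
    ratios
        Per-protein log2 enrichment ratios for the condition, indexed by
        protein id.
    annotations
        Flat map with columns ``protein_id`` and ``category``.  Annotated
        proteins absent from ``ratios`` are dropped.
    min_size
        Categories with fewer mapped members are excluded from testing but
        still reported (``tested`` False).

    Returns a frame sorted by Bonferroni-adjusted p:
    ``category condition n_in n_out statistic p p_bonf direction
    significant tested``.  The Bonferroni factor is the number of
    categories actually tested; ``significant`` means ``p_bonf < alpha``.
    """
    ratios = ratios.dropna()
    known = set(ratios.index)
    mapped = annotations.loc[annotations["protein_id"].isin(known)]
    values = ratios.to_numpy(dtype=float)
    index_of = {pid: i for i, pid in enumerate(ratios.index)}

    rows = []
    for category, members in mapped.groupby("category")["protein_id"]:
        idx = np.array(sorted({index_of[p] for p in members}), dtype=int)
        n_in, n_out = idx.size, values.size - idx.size
        testable = n_in >= min_size and n_out >= 1
        if testable:
            mask = np.zeros(values.size, dtype=bool)
            mask[idx] = True
            res = rank_sum_test(values[mask], values[~mask])
            rows.append(
                (category, condition, n_in, n_out, res.statistic, res.p_two_sided,
                 res.direction, True)
            )
        else:
            rows.append((category, condition, n_in, n_out, np.nan, np.nan, "", False))
    out = pd.DataFrame(
        rows,
        columns=["category", "condition", "n_in", "n_out", "statistic", "p",
                 "direction", "tested"],
    )
    m = int(out["tested"].sum())
    out["p_bonf"] = np.where(out["tested"], np.minimum(1.0, out["p"] * max(m, 1)), np.nan)
    out["significant"] = out["tested"] & (out["p_bonf"] < alpha)
    out = out.sort_values(
        ["tested", "p_bonf", "category"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return out[["category", "condition", "n_in", "n_out", "statistic", "p",
                "p_bonf", "direction", "significant", "tested"]]
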