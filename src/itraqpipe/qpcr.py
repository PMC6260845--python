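"""Livak 2^-ddCt relative qPCR quantification and protein-mRNA concordance.

The Livak method quantifies a target gene's expression relative to
reference genes and to a control condition, assuming amplification
efficiency 2 (one cycle per doubling):

    dCt   = Ct_target - mean(Ct over reference genes)
    ddCt  = mean(dCt_treated) - mean(dCt_control)
    fold  = 2 ** -ddCt

With two reference genes (here PP2Acs and clat), the arithmetic mean of
their Cts corresponds to normalizing by the geometric mean of the
reference quantities, the standard multi-reference practice.  Group
statistics (one-way ANOVA followed by Tukey HSD pairwise comparisons
against Control) run on dCt values, which are approximately normal,
rather than on the log-normally distributed folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import CONDITIONS

__all__ = [
    "DEFAULT_REFERENCE_GENES",
    "FoldChange",
    "collapse_technical",
    "delta_ct",
    "livak_fold",
    "compare_groups",
    "livak_table",
    "concordance",
]

DEFAULT_REFERENCE_GENES: tuple[str, ...] = ("PP2Acs", "clat")


def collapse_technical(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates to one Ct per (gene, condition, bio_rep)."""
    out = (
        ct_table.groupby(["gene", "condition", "bio_rep"], sort=True)["ct"]
        .mean()
        .reset_index()
    )
    return out


def delta_ct(
    collapsed: pd.DataFrame, reference_genes=DEFAULT_REFERENCE_GENES
) -> pd.DataFrame:
    """dCt = target Ct - arithmetic mean of the reference genes' Cts.

    Computed per (target gene, condition, bio_rep).  Replicates missing
    any reference measurement are dropped (count in ``attrs['n_dropped']``).
    """
    refs = collapsed.loc[collapsed["gene"].isin(reference_genes)]
    if refs.empty:
        raise ValueError(f"no reference-gene rows found for {tuple(reference_genes)}")
    ref_n = refs.groupby(["condition", "bio_rep"])["gene"].nunique()
    ref_mean = refs.groupby(["condition", "bio_rep"])["ct"].mean()
    complete = ref_n[ref_n == len(set(reference_genes))].index

    targets = collapsed.loc[~collapsed["gene"].isin(reference_genes)].copy()
    key = pd.MultiIndex.from_frame(targets[["condition", "bio_rep"]])
    keep = key.isin(complete)
    n_dropped = int((~keep).sum())
    targets = targets.loc[keep]
    key = key[keep]
    targets["delta_ct"] = targets["ct"].to_numpy() - ref_mean.loc[key].to_numpy()
    out = targets[["gene", "condition", "bio_rep", "delta_ct"]].reset_index(drop=True)
    out.attrs["n_dropped"] = n_dropped
    return out


@dataclass(frozen=True)
class FoldChange:
    """Relative expression 2^-ddCt of one gene in one condition vs Control."""

    fold: float
    log2_fold: float
    ddct: float
    per_rep_folds: tuple[float, ...]
    sd: float
    n: int


def livak_fold(dct_treated, dct_control) -> FoldChange:
    """Livak relative quantification from per-replicate dCt values.

    ``ddCt = mean(dCt_treated) - mean(dCt_control)``; ``fold = 2**-ddCt``.
    Per-replicate folds ``2**-(dCt_i - mean(dCt_control))`` are retained
    for error bars; ``sd`` is their sample SD (0 when n = 1).
    """
    t = np.asarray(dct_treated, dtype=float)
    c = np.asarray(dct_control, dtype=float)
    if t.size < 1 or c.size < 1:
        raise ValueError("both dCt groups must be non-empty")
    ddct = float(t.mean() - c.mean())
    fold = float(2.0 ** -ddct)
    per_rep = 2.0 ** -(t - c.mean())
    sd = float(per_rep.std(ddof=1)) if t.size > 1 else 0.0
    return FoldChange(fold, float(np.log2(fold)), ddct, tuple(per_rep), sd, int(t.size))


def compare_groups(
    dct: pd.DataFrame, control: str = "Control", alpha: float = 0.05
) -> pd.DataFrame:
    """One-way ANOVA on dCt across conditions, then Tukey HSD vs Control.

    Expects one gene's dCt frame (columns ``condition``, ``delta_ct``).
    Returns per non-control condition: the Tukey-adjusted p-value of the
    contrast against Control and its significance at ``alpha``.  When every
    group has zero within-group variance the studentized range is
    undefined; any between-group mean difference is then flagged
    significant with p 0 (degenerate case), identical means with p 1.
    """
    groups = {c: g["delta_ct"].to_numpy(dtype=float) for c, g in dct.groupby("condition")}
    if control not in groups:
        raise ValueError(f"control condition {control!r} absent")
    if len(groups) < 2 or any(v.size < 2 for v in groups.values()):
        raise ValueError("need >= 2 groups with >= 2 replicates each")
    names = [control] + sorted(c for c in groups if c != control)
    arrays = [groups[c] for c in names]

    pooled_var = np.mean([v.var(ddof=1) for v in arrays])
    rows = []
    if pooled_var == 0.0:
        for c in names[1:]:
            diff = float(groups[c].mean() - groups[control].mean())
            p = 0.0 if diff != 0 else 1.0
            rows.append((c, p, p <= alpha and diff != 0, True))
    else:
        f_stat, anova_p = stats.f_oneway(*arrays)
        tukey = stats.tukey_hsd(*arrays)
        for i, c in enumerate(names[1:], start=1):
            p = float(tukey.pvalue[0, i])
            rows.append((c, p, p <= alpha, False))
    out = pd.DataFrame(rows, columns=["condition", "p_tukey", "significant", "degenerate"])
    return out


def livak_table(
    ct_table: pd.DataFrame,
    reference_genes=DEFAULT_REFERENCE_GENES,
    control: str = "Control",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full qPCR analysis: folds and Tukey significance for every gene x condition.

    Returns ``gene condition fold log2_fold ddct sd n significant p_tukey``.
    """
    collapsed = collapse_technical(ct_table)
    dct = delta_ct(collapsed, reference_genes)
    rows = []
    for gene, g in dct.groupby("gene"):
        ctrl = g.loc[g["condition"] == control, "delta_ct"].to_numpy(dtype=float)
        if ctrl.size == 0:
            continue
        try:
            comp = compare_groups(g, control=control, alpha=alpha)
            pmap = comp.set_index("condition")
        except ValueError:
            pmap = pd.DataFrame(columns=["p_tukey", "significant"])
        for cond in CONDITIONS:
            if cond == control:
                continue
            treated = g.loc[g["condition"] == cond, "delta_ct"].to_numpy(dtype=float)
            if treated.size == 0:
                continue
            fc = livak_fold(treated, ctrl)
            p = float(pmap["p_tukey"].get(cond, np.nan))
            sig = bool(pmap["significant"].get(cond, False))
            rows.append(
                (gene, cond, fc.fold, fc.log2_fold, fc.ddct, fc.sd, fc.n, sig, p)
            )
    return pd.DataFrame(
        rows,
        columns=["gene", "condition", "fold", "log2_fold", "ddct", "sd", "n",
                 "significant", "p_tukey"],
    )


def concordance(
    calls: pd.DataFrame, folds: pd.DataFrame, gene_protein_map: dict[str, str]
) -> pd.DataFrame:
    """Protein vs mRNA direction agreement per gene and condition.

    The protein direction comes from the differential calls (up/down/none);
    the mRNA direction is up (down) when the Livak fold is significantly
    above (below) 1, else none.  A pair is concordant when both directions
    are equal and non-none, or both are none.  Genes without a protein
    mapping are skipped.
    """
    call_dir = {
        (r.protein_id, r.condition): r.direction for r in calls.itertuples(index=False)
    }
    rows = []
    for r in folds.itertuples(index=False):
        pid = gene_protein_map.get(r.gene)
        if pid is None:
            continue
        mrna = "none"
        if r.significant:
            mrna = "up" if r.fold > 1 else "down"
        prot = call_dir.get((pid, r.condition), "none")
        rows.append((r.gene, pid, r.condition, prot, mrna, prot == mrna))
    return pd.DataFrame(
        rows,
        columns=["gene", "protein_id", "condition", "protein_direction",
                 "mrna_direction", "concordant"],
    )
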