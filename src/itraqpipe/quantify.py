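"""Peptide filtering, channel normalization and intensity-weighted protein rollup.

The quantification chain mirrors standard isobaric-reporter practice:

1. keep peptide-spectrum evidence with search expectation value < 0.05
   (and, by default, only peptides unique to one protein),
2. global ratio normalization (summed): rescale each reporter channel so
   all channel sums are equal, correcting unequal loading,
3. roll peptides up to proteins by summing reporter intensities per
   channel -- the intensity-weighted protein ratio, since summing weights
   each peptide's ratio by its intensity,
4. drop proteins with fewer than two unique peptides,
5. divide each treated channel by its paired control channel to obtain
   per-replicate enrichment ratios, summarized per condition by the
   geometric mean.

Missing reporter values are omitted from sums, never imputed as zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import CHANNELS, INTENSITY_COLUMNS, REPLICATES, TREATMENTS, DesignMap

__all__ = [
    "NormalizationError",
    "filter_peptides",
    "normalize_channels",
    "rollup_protein",
    "filter_proteins",
    "compute_enrichment",
]


class NormalizationError(ValueError):
    """Raised when a reporter channel cannot be normalized (zero/absent signal)."""


def filter_peptides(
    table: pd.DataFrame, e_max: float = 0.05, unique_only: bool = True
) -> pd.DataFrame:
    """Keep rows with ``expect_value`` strictly below ``e_max``.

    With ``unique_only`` (default), shared peptides (``is_unique`` False)
    are dropped as well; only unique peptides then contribute to
    quantification.  Input row order is preserved; the result may be empty.
    """
    if not e_max > 0:
        raise ValueError("e_max must be > 0")
    keep = table["expect_value"] < e_max
    if unique_only:
        keep &= table["is_unique"].astype(bool)
    return table.loc[keep].copy()


def normalize_channels(table: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, float]]:
    """Global ratio normalization (summed): equalize reporter-channel sums.

    Each channel ``c`` is multiplied by
    ``f_c = (grand mean of channel sums) / (sum of channel c)``, computed
    over non-missing entries, so that after scaling every channel sums to
    the grand mean of the pre-normalization sums.  Returns the scaled table
    and the per-channel factors.

    Raises
    ------
    NormalizationError
        If a channel has no signal (all missing, or zero total), naming it.
    """
    sums = {}
    for ch, col in zip(CHANNELS, INTENSITY_COLUMNS):
        s = table[col].sum(skipna=True)
        if not np.isfinite(s) or s <= 0 or table[col].notna().sum() == 0:
            raise NormalizationError(f"channel {ch} has no usable intensity (sum={s})")
        sums[ch] = float(s)
    grand = float(np.mean(list(sums.values())))
    factors = {ch: grand / sums[ch] for ch in CHANNELS}
    out = table.copy()
    for ch, col in zip(CHANNELS, INTENSITY_COLUMNS):
        out[col] = out[col] * factors[ch]
    return out, factors


def rollup_protein(table: pd.DataFrame) -> pd.DataFrame:
    """Roll peptide evidence up to per-protein, per-channel abundances.

    ``abundance[c]`` is the sum of the protein's peptide intensities in
    channel ``c``, peptides missing that channel being omitted from the
    sum (a protein with no peptide covering a channel gets NaN there).
    Summing is the intensity-weighted protein ratio: the protein-level
    ratio between two channels equals the intensity-weighted mean of the
    peptide ratios, and the common per-protein total cancels in every
    downstream ratio.

    Returns a DataFrame indexed by ``protein_id`` with the 8 abundance
    columns (named as the intensity columns), ``n_unique_peptides``
    (distinct unique-flagged peptide sequences) and ``n_peptides_used``.
    """
    if table.empty:
        cols = list(INTENSITY_COLUMNS) + ["n_unique_peptides", "n_peptides_used"]
        return pd.DataFrame(columns=cols, index=pd.Index([], name="protein_id"))
    grouped = table.groupby("protein_id", sort=True)
    abund = grouped[list(INTENSITY_COLUMNS)].sum(min_count=1)
    uniq = (
        table.loc[table["is_unique"].astype(bool)]
        .groupby("protein_id")["peptide_seq"]
        .nunique()
        .reindex(abund.index, fill_value=0)
    )
    quants = abund.copy()
    quants["n_unique_peptides"] = uniq.astype(int)
    quants["n_peptides_used"] = grouped.size().astype(int)
    quants.index.name = "protein_id"
    return quants


def filter_proteins(quants: pd.DataFrame, min_unique: int = 2) -> pd.DataFrame:
    """Quality filter: keep proteins with >= ``min_unique`` unique peptides."""
    if min_unique < 1:
        raise ValueError("min_unique must be >= 1")
    return quants.loc[quants["n_unique_peptides"] >= min_unique].copy()


def compute_enrichment(
    quants: pd.DataFrame, design: DesignMap, pairing: str = "by_replicate"
) -> pd.DataFrame:
    """Treatment/control enrichment ratios per protein.

    ``by_replicate`` (default) divides each treated channel by the control
    channel of the *same* replicate index: ``ratio(cond, rep) =
    abundance(cond, rep) / abundance(Control, rep)``.  ``by_control_mean``
    divides every treated channel by the geometric mean of the two control
    channels.  The per-condition summary ratio is the geometric mean of the
    available replicate ratios.  Cells whose control (or treated) abundance
    is missing or nonpositive are NaN.

    Returns a DataFrame indexed by ``protein_id`` with columns
    ``burned_r1 burned_r2 limit_r1 limit_r2 regular_r1 regular_r2`` and the
    summaries ``burned limit regular``.
    """
    if pairing not in ("by_replicate", "by_control_mean"):
        raise ValueError(f"unknown pairing {pairing!r}")
    ctrl = {
        rep: quants[f"i{design.channel('Control', rep)}"].to_numpy(dtype=float)
        for rep in REPLICATES
    }
    for rep in REPLICATES:
        ctrl[rep] = np.where(ctrl[rep] > 0, ctrl[rep], np.nan)
    if pairing == "by_control_mean":
        with np.errstate(invalid="ignore"):
            gm = np.exp2(np.nanmean(np.log2(np.column_stack(list(ctrl.values()))), axis=1))
        ctrl = {rep: gm for rep in REPLICATES}

    out = pd.DataFrame(index=quants.index.copy())
    for cond in TREATMENTS:
        cols = []
        for rep in REPLICATES:
            treated = quants[f"i{design.channel(cond, rep)}"].to_numpy(dtype=float)
            treated = np.where(treated > 0, treated, np.nan)
            col = f"{cond.lower()}_r{rep}"
            out[col] = treated / ctrl[rep]
            cols.append(col)
        with np.errstate(invalid="ignore", divide="ignore"):
            log2r = np.log2(out[cols].to_numpy(dtype=float))
        present = np.isfinite(log2r)
        n_present = present.sum(axis=1)
        total = np.where(present, log2r, 0.0).sum(axis=1)
        summary = np.full(len(out), np.nan)
        has = n_present > 0
        summary[has] = np.exp2(total[has] / n_present[has])
        out[cond.lower()] = summary
    return out
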