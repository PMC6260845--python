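"""Empirical replicate-ratio null, differential calling and set partition.

Significance is anchored to an empirical distribution of total experimental
variability: for every protein and every condition (Control included), the
ratio of the two biological replicates' abundances is computed, and all
these ratios are pooled into one empirical CDF regardless of condition.
Since a true condition effect is common to both replicates it cancels in
the ratio, so the pooled sample reflects biological-plus-technical
variability only.

From the pooled sample the model records the mean and SD of the log2
ratios, the 2-SD fold-change cutoffs ``2**(mu +/- 2*sigma)`` used for
calling, and the descriptive central-90% interval (the scale on which 90%
of replicate ratios fell between 0.61 and 1.61 in the motivating dataset).
A protein/condition is called differential when its summary enrichment
ratio lies strictly outside the cutoff interval AND its
Benjamini-Hochberg-adjusted empirical p-value is at most alpha.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .design import REPLICATES, TREATMENTS, DesignMap

__all__ = [
    "NullSample",
    "NullModel",
    "VennPartition",
    "replicate_ratios",
    "fit_null",
    "empirical_pvalue",
    "call_differential",
    "partition_sets",
]


@dataclass
class NullSample:
    """Pooled replicate ratios (rep1/rep2), with provenance and a skip count."""

    ratios: pd.DataFrame  # columns: protein_id, condition, ratio
    n_skipped: int = 0

    @property
    def values(self) -> np.ndarray:
        return self.ratios["ratio"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.ratios)


def replicate_ratios(quants: pd.DataFrame, design: DesignMap) -> NullSample:
    """Within-condition replicate ratios for every protein, pooled over conditions.

    For each protein and condition with both replicate abundances present,
    emits ``abundance(rep1) / abundance(rep2)`` (replicate order from the
    design map).  Protein/condition pairs missing a replicate are skipped
    and counted in ``n_skipped``.
    """
    frames = []
    n_skipped = 0
    conditions = sorted({cond for _, cond, _ in design.assignments})
    for cond in conditions:
        a1 = quants[f"i{design.channel(cond, REPLICATES[0])}"].to_numpy(dtype=float)
        a2 = quants[f"i{design.channel(cond, REPLICATES[1])}"].to_numpy(dtype=float)
        ok = np.isfinite(a1) & np.isfinite(a2) & (a1 > 0) & (a2 > 0)
        n_skipped += int((~ok).sum())
        frames.append(
            pd.DataFrame(
                {
                    "protein_id": quants.index.to_numpy()[ok],
                    "condition": cond,
                    "ratio": a1[ok] / a2[ok],
                }
            )
        )
    pooled = pd.concat(frames, ignore_index=True)
    return NullSample(pooled, n_skipped)


@dataclass
class NullModel:
    """Empirical CDF of replicate log2 ratios with 2-SD fold-change cutoffs.

    Attributes
    ----------
    mu, sigma
        Mean and SD of the pooled log2 ratios.
    cutoff_low, cutoff_high
        ``2**(mu - 2*sigma)`` and ``2**(mu + 2*sigma)`` on the ratio scale.
        Log-symmetric: ``cutoff_low * cutoff_high == 2**(2*mu)`` exactly.
    central90
        Empirical 5th and 95th percentiles of the ratios (linear
        interpolation between order statistics).
    """

    mu: float
    sigma: float
    cutoff_low: float
    cutoff_high: float
    central90: tuple[float, float]
    n: int
    log2_ratios: np.ndarray = field(repr=False)
    _abs_dev: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self._abs_dev is None:
            self._abs_dev = np.sort(np.abs(self.log2_ratios - self.mu))

    @property
    def degenerate(self) -> bool:
        return self.sigma == 0.0

    def cdf(self, ratio: float | np.ndarray) -> float | np.ndarray:
        """Empirical CDF of the null, evaluated on the ratio scale."""
        x = np.log2(np.asarray(ratio, dtype=float))
        srt = np.sort(self.log2_ratios)
        return np.searchsorted(srt, x, side="right") / self.n

    def to_dict(self) -> dict:
        return {
            "mu": self.mu,
            "sigma": self.sigma,
            "cutoff_low": self.cutoff_low,
            "cutoff_high": self.cutoff_high,
            "central90": list(self.central90),
            "n": self.n,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def fit_null(sample: NullSample | np.ndarray, min_n: int = 10, scale: str = "log2") -> NullModel:
    """Fit the empirical null from pooled replicate ratios.

    ``scale="log2"`` (default) computes mean/SD on the log2 ratio scale,
    which is reciprocal-symmetric; ``scale="ratio"`` is the raw-ratio
    variant (asymmetric; provided for comparison only).  SD uses the
    population convention (ddof=0).  ``sigma == 0`` yields a degenerate
    model whose cutoffs coincide.
    """
    values = sample.values if isinstance(sample, NullSample) else np.asarray(sample, float)
    if np.any(values <= 0) or not np.all(np.isfinite(values)):
        raise ValueError("null ratios must be finite and > 0")
    n = values.size
    if n < min_n:
        raise ValueError(
            f"null sample too small (n={n} < {min_n}); quantify more proteins "
            "or lower min_n"
        )
    log2r = np.log2(values)
    if scale == "log2":
        mu = float(np.mean(log2r))
        sigma = float(np.std(log2r))
        lo, hi = 2.0 ** (mu - 2 * sigma), 2.0 ** (mu + 2 * sigma)
    elif scale == "ratio":
        m = float(np.mean(values))
        s = float(np.std(values))
        mu, sigma = float(np.log2(m)), s  # sigma kept on the ratio scale
        lo, hi = m - 2 * s, m + 2 * s
    else:
        raise ValueError(f"unknown scale {scale!r}")
    central90 = tuple(np.quantile(values, [0.05, 0.95], method="linear"))
    return NullModel(
        mu=mu,
        sigma=sigma,
        cutoff_low=float(lo),
        cutoff_high=float(hi),
        central90=(float(central90[0]), float(central90[1])),
        n=n,
        log2_ratios=log2r,
    )


def empirical_pvalue(
    ratio: float | np.ndarray, model: NullModel, n_reps: int = 1
) -> float | np.ndarray:
    """Two-sided empirical p-value of a fold change against the null.

    With ``n_reps=1``, an add-one (permutation-style) tail count on the
    log2 scale::

        p = (1 + #{null log2 ratios x : |x - mu| >= |log2(ratio) - mu|}) / (n + 1)

    so p is in ``(0, 1]``, equals 1 at the null center and never reaches 0.

    ``n_reps=2`` matches the null to a statistic that averages two
    replicate ratios: under the null the tested log2 ratio is the mean of
    two independent draws from the replicate-ratio distribution, so the
    reference becomes the empirical 2-fold convolution -- the tail is
    counted over all ordered *pairs* of null ratios::

        p = (1 + #{(i, j) : |(x_i + x_j)/2 - mu| >= dev}) / (n**2 + 1)

    Testing a two-replicate mean against single-draw ratios would be
    conservative by a factor sqrt(2) in scale.

    For a degenerate model (sigma = 0), p is 1 at ``ratio == 2**mu`` and
    the add-one floor elsewhere.
    """
    if n_reps not in (1, 2):
        raise ValueError("n_reps must be 1 or 2")
    r = np.asarray(ratio, dtype=float)
    if np.any(r[np.isfinite(r)] <= 0):
        raise ValueError("ratio must be > 0")
    dev = np.abs(np.log2(r) - model.mu)
    n_pairs = model.n if n_reps == 1 else model.n**2
    if model.degenerate:
        p = np.where(dev == 0, 1.0, 1.0 / (n_pairs + 1))
    elif n_reps == 1:
        # count of |x - mu| >= dev via the pre-sorted deviations
        count = model.n - np.searchsorted(model._abs_dev, dev, side="left")
        p = (1.0 + count) / (model.n + 1.0)
    else:
        count = _pair_tail_count(np.sort(model.log2_ratios), model.mu, np.atleast_1d(dev))
        p = np.minimum(1.0, (1.0 + count) / (n_pairs + 1.0))
        if dev.ndim == 0:
            p = p[0]
    p = np.where(np.isfinite(r), p, np.nan)
    return float(p) if np.isscalar(ratio) else p


def _pair_tail_count(xs: np.ndarray, mu: float, dev: np.ndarray) -> np.ndarray:
    """#{ordered pairs (i, j): |(x_i + x_j)/2 - mu| >= d} for each d, exactly.

    ``xs`` must be sorted.  Computed with two binary-search passes per
    query, chunked to bound memory.
    """
    n = xs.size
    out = np.empty(dev.shape, dtype=np.int64)
    chunk = max(1, int(4e6) // max(n, 1))
    for start in range(0, dev.size, chunk):
        d = dev[start : start + chunk]
        thr_hi = 2.0 * (mu + d)[:, None] - xs[None, :]  # x_j >= thr -> upper tail
        upper = (n - np.searchsorted(xs, thr_hi, side="left")).sum(axis=1)
        thr_lo = 2.0 * (mu - d)[:, None] - xs[None, :]  # x_j <= thr -> lower tail
        lower = np.searchsorted(xs, thr_lo, side="right").sum(axis=1)
        out[start : start + chunk] = upper + lower
    return out


def call_differential(
    enrichment: pd.DataFrame,
    model: NullModel,
    alpha: float = 0.05,
    interval: str = "2sd",
    family: str = "per_condition",
    n_reps: int = 2,
) -> pd.DataFrame:
    """Call differential proteins per condition.

    A call is significant iff its per-condition summary ratio is strictly
    outside the interval (``2sd`` cutoffs by default, or the descriptive
    ``central90`` interval) AND its BH-adjusted empirical p-value is at
    most ``alpha``.  BH runs within each condition (``per_condition``,
    default) or over all three at once (``global``).  ``n_reps`` is
    forwarded to :func:`empirical_pvalue`: the default 2 matches the null
    to the summary ratio, which is the geometric mean of two replicate
    ratios (``n_reps=1`` tests against raw single-replicate ratios, which
    is conservative).  Missing ratios yield rows with ``significant``
    False and ``reason`` "missing".

    Returns a tidy frame: ``protein_id condition ratio log2_ratio p q
    significant direction reason``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if interval == "2sd":
        lo, hi = model.cutoff_low, model.cutoff_high
    elif interval == "central90":
        lo, hi = model.central90
    else:
        raise ValueError(f"unknown interval {interval!r}")

    rows = []
    for cond in TREATMENTS:
        ratio = enrichment[cond.lower()].to_numpy(dtype=float)
        ok = np.isfinite(ratio) & (ratio > 0)
        p = np.full(ratio.shape, np.nan)
        p[ok] = np.atleast_1d(empirical_pvalue(ratio[ok], model, n_reps=n_reps))
        rows.append(
            pd.DataFrame(
                {
                    "protein_id": enrichment.index.to_numpy(),
                    "condition": cond,
                    "ratio": ratio,
                    "log2_ratio": np.where(ok, np.log2(np.where(ok, ratio, 1.0)), np.nan),
                    "p": p,
                }
            )
        )
    calls = pd.concat(rows, ignore_index=True)

    calls["q"] = np.nan
    if family == "per_condition":
        groups = [calls["condition"] == c for c in TREATMENTS]
    elif family == "global":
        groups = [pd.Series(True, index=calls.index)]
    else:
        raise ValueError(f"unknown family {family!r}")
    for g in groups:
        mask = g & calls["p"].notna()
        if mask.any():
            calls.loc[mask, "q"] = multipletests(calls.loc[mask, "p"], method="fdr_bh")[1]

    ok = calls["ratio"].notna() & (calls["ratio"] > 0)
    outside = ok & ((calls["ratio"] < lo) | (calls["ratio"] > hi))
    calls["significant"] = outside & (calls["q"] <= alpha)
    calls["direction"] = "none"
    calls.loc[calls["significant"] & (calls["ratio"] > hi), "direction"] = "up"
    calls.loc[calls["significant"] & (calls["ratio"] < lo), "direction"] = "down"
    calls["reason"] = np.where(ok, "", "missing")
    return calls


@dataclass
class VennPartition:
    """Exact 7-region partition of the three per-condition significant sets."""

    regions: dict[str, set[str]]

    _KEYS = (
        "Burned_only",
        "Limit_only",
        "Regular_only",
        "Burned_Limit",
        "Burned_Regular",
        "Limit_Regular",
        "all_three",
    )

    @property
    def counts(self) -> dict[str, int]:
        return {k: len(self.regions[k]) for k in self._KEYS}

    def to_dict(self) -> dict:
        return {k: sorted(self.regions[k]) for k in self._KEYS}


def partition_sets(calls: pd.DataFrame) -> VennPartition:
    """Partition significant proteins into the 7 Venn regions of the 3 conditions."""
    sets = {
        cond: set(calls.loc[(calls["condition"] == cond) & calls["significant"], "protein_id"])
        for cond in TREATMENTS
    }
    b, l, r = sets["Burned"], sets["Limit"], sets["Regular"]
    regions = {
        "Burned_only": b - l - r,
        "Limit_only": l - b - r,
        "Regular_only": r - b - l,
        "Burned_Limit": (b & l) - r,
        "Burned_Regular": (b & r) - l,
        "Limit_Regular": (l & r) - b,
        "all_three": b & l & r,
    }
    return VennPartition(regions)
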