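"""Synthetic LC-MS/MS benchmark data with known ground truth.

Real raw data for the tomato extreme-high-light study is not deposited, so
every downstream stage is exercised on simulated inputs whose true fold
changes, pattern labels and differential flags are known.  The generator
emulates the structure of an iTRAQ 8-plex experiment:

* log-normal protein base abundances,
* per-condition true log2 fold changes drawn from four pattern archetypes
  (Burned-high; Limit-high; monotone decreasing with light dose; flat or
  slightly Regular-leaning),
* log-normal peptide ionization efficiencies (1..20 peptides per protein,
  a fraction shared between proteins),
* unequal channel loading, multiplicative reporter noise, biological
  between-replicate variation,
* threshold censoring of low intensities,
* search expectation values straddling the 0.05 quality cutoff,
* qPCR Ct tables with reference-gene structure.

All noise is multiplicative (additive on the log2 scale), which keeps
analytic oracles available for the tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .design import CHANNELS, CONDITIONS, INTENSITY_COLUMNS, TREATMENTS, DesignMap

__all__ = [
    "SimParams",
    "CtSimParams",
    "generate_ground_truth",
    "simulate_peptide_table",
    "simulate_ct_table",
    "simulate_annotations",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Archetype labels; "none" marks proteins with no condition effect.
PATTERNS = ("1", "2", "3", "4")


@dataclass(frozen=True)
class SimParams:
    """Parameters of the peptide-evidence simulation.

    Defaults are calibrated to the study conditions: ``sigma_rep`` = 0.3
    gives a replicate-ratio null whose central 90% interval is close to the
    (0.61, 1.61) scale observed between biological replicates;
    ``pattern_weights`` and ``frac_null`` follow the observed proportions of
    the four expression patterns among quantified proteins; ``effect_size``
    is log2(2.5), a clearly-detectable enrichment.
    """

    n_proteins: int = 2000
    peptide_count_range: tuple[int, int] = (1, 20)
    frac_shared_peptides: float = 0.15
    frac_expect_fail: float = 0.10
    channel_loading: tuple[float, ...] = (1.0, 0.92, 1.08, 0.95, 1.05, 0.90, 1.10, 0.98)
    sigma_protein: float = 1.5
    sigma_peptide: float = 1.0
    sigma_noise: float = 0.25
    sigma_rep: float = 0.3
    pattern_weights: tuple[float, float, float, float] = (0.042, 0.038, 0.005, 0.915)
    effect_size: float = math.log2(2.5)
    frac_null: float = 0.33
    missing_intensity_threshold: float = 30000.0
    mean_log2_abundance: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_shared_peptides", "frac_expect_fail", "frac_null"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("sigma_protein", "sigma_peptide", "sigma_noise", "sigma_rep"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if len(self.channel_loading) != len(CHANNELS):
            raise ValueError("channel_loading needs one factor per channel")
        if any(f <= 0 for f in self.channel_loading):
            raise ValueError("channel_loading factors must be > 0")
        if len(self.pattern_weights) != 4 or any(w < 0 for w in self.pattern_weights):
            raise ValueError("pattern_weights must be 4 nonnegative weights")
        if abs(sum(self.pattern_weights) - 1.0) > 1e-9:
            raise ValueError("pattern_weights must sum to 1 within 1e-9")
        lo, hi = self.peptide_count_range
        if not (1 <= lo <= hi):
            raise ValueError("peptide_count_range must satisfy 1 <= lo <= hi")
        if self.n_proteins < 0:
            raise ValueError("n_proteins must be >= 0")

    def with_seed(self, seed: int) -> "SimParams":
        return replace(self, seed=seed)


def _protein_ids(n: int) -> list[str]:
    return [f"P{i:05d}" for i in range(1, n + 1)]


def generate_ground_truth(params: SimParams) -> pd.DataFrame:
    """Draw per-protein pattern labels and true log2 fold changes vs Control.

    Archetype fold-change vectors over (Burned, Limit, Regular), with
    ``e = effect_size``:

    * pattern 1: ``(e, 0, 0)`` -- Burned-high
    * pattern 2: ``(0, e, 0)`` -- Limit-high
    * pattern 3: ``(e, e/2, e/4)`` -- decreasing with light dose
    * pattern 4: ``(0, 0, u)`` with ``u ~ U(0, e/4]`` -- flat, slightly
      Regular-leaning

    A ``frac_null`` fraction of proteins gets pattern "none" with all fold
    changes zero.  Returns a DataFrame with columns ``protein_id``,
    ``pattern``, ``fc_burned``, ``fc_limit``, ``fc_regular`` and boolean
    ``diff_burned``/``diff_limit``/``diff_regular`` flags (|FC| > 0).
    """
    if params.n_proteins == 0:
        raise ValueError("cannot generate ground truth for n_proteins = 0")
    rng = np.random.default_rng(params.seed)
    n = params.n_proteins
    e = params.effect_size

    probs = np.concatenate(
        [[params.frac_null], (1.0 - params.frac_null) * np.asarray(params.pattern_weights)]
    )
    labels = np.array(["none", "1", "2", "3", "4"])
    pattern = labels[rng.choice(5, size=n, p=probs / probs.sum())]

    fc = np.zeros((n, 3))
    fc[pattern == "1"] = (e, 0.0, 0.0)
    fc[pattern == "2"] = (0.0, e, 0.0)
    fc[pattern == "3"] = (e, e / 2.0, e / 4.0)
    n4 = int((pattern == "4").sum())
    if n4:
        u = rng.uniform(0.0, e / 4.0, size=n4)
        u = np.maximum(u, 1e-6)  # keep "small positive" strictly positive
        fc[pattern == "4", 2] = u

    truth = pd.DataFrame(
        {
            "protein_id": _protein_ids(n),
            "pattern": pattern,
            "fc_burned": fc[:, 0],
            "fc_limit": fc[:, 1],
            "fc_regular": fc[:, 2],
        }
    )
    for cond in TREATMENTS:
        truth[f"diff_{cond.lower()}"] = truth[f"fc_{cond.lower()}"].abs() > 0
    return truth


def simulate_peptide_table(
    truth: pd.DataFrame, params: SimParams
) -> tuple[pd.DataFrame, DesignMap]:
    """Simulate a peptide-evidence table from ground truth.

    For each protein, a peptide count is drawn uniformly from
    ``peptide_count_range``; the reporter intensity of peptide ``p`` in
    channel ``c`` is::

        2 ** (base + FC(condition(c)) + rep_effect + ion_eff + noise) * loading(c)

    with ``base ~ N(mean_log2_abundance, sigma_protein)`` per protein,
    ``rep_effect ~ N(0, sigma_rep)`` per (protein, condition, replicate),
    ``ion_eff ~ N(0, sigma_peptide)`` per peptide and
    ``noise ~ N(0, sigma_noise)`` per peptide x channel.  Intensities below
    ``missing_intensity_threshold`` are censored to missing (NaN).
    """
    if len(truth) != params.n_proteins:
        raise ValueError("truth and params disagree on n_proteins")
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    design = DesignMap.default()
    n = params.n_proteins
    lo, hi = params.peptide_count_range

    counts = rng.integers(lo, hi + 1, size=n)
    m = int(counts.sum())
    prot_idx = np.repeat(np.arange(n), counts)

    base = rng.normal(params.mean_log2_abundance, params.sigma_protein, size=n)
    rep_eff = rng.normal(0.0, params.sigma_rep, size=(n, len(CONDITIONS), 2))
    ion = rng.normal(0.0, params.sigma_peptide, size=m)
    noise = rng.normal(0.0, params.sigma_noise, size=(m, len(CHANNELS)))

    # per-protein log2 FC indexed by condition (Control = 0)
    fc_by_cond = np.zeros((n, len(CONDITIONS)))
    for j, cond in enumerate(CONDITIONS):
        if cond != "Control":
            fc_by_cond[:, j] = truth[f"fc_{cond.lower()}"].to_numpy()

    log2_int = np.empty((m, len(CHANNELS)))
    for k, ch in enumerate(CHANNELS):
        cond, rep = design.sample(ch)
        j = CONDITIONS.index(cond)
        log2_int[:, k] = (
            base[prot_idx]
            + fc_by_cond[prot_idx, j]
            + rep_eff[prot_idx, j, rep - 1]
            + ion
            + noise[:, k]
        )
    intensity = np.exp2(log2_int) * np.asarray(params.channel_loading)
    intensity[intensity < params.missing_intensity_threshold] = np.nan

    is_unique = rng.random(m) >= params.frac_shared_peptides
    expect = rng.uniform(1e-6, 0.05, size=m)
    fail = rng.random(m) < params.frac_expect_fail
    expect[fail] = rng.uniform(0.05, 1.0, size=int(fail.sum()))

    ids = np.asarray(truth["protein_id"])
    table = pd.DataFrame(
        {
            "protein_id": ids[prot_idx],
            "peptide_seq": [_peptide_seq(i) for i in range(m)],
            "is_unique": is_unique,
            "expect_value": expect,
        }
    )
    for k, col in enumerate(INTENSITY_COLUMNS):
        table[col] = intensity[:, k]
    return table, design


def _peptide_seq(index: int, length: int = 9) -> str:
    """Deterministic pseudo-tryptic sequence; unique per row index."""
    chars = []
    x = index
    for _ in range(length - 1):
        chars.append(_AA[x % len(_AA)])
        x //= len(_AA)
    return "".join(reversed(chars)) + "K"


@dataclass(frozen=True)
class CtSimParams:
    """Parameters of the qPCR Ct simulation.

    Ct values (PCR cycles to threshold) decrease by one cycle per doubling
    of template, so a true fold ``f`` vs Control shifts the mean Ct by
    ``-log2(f)``.  ``sigma_sample`` is a per-(condition, biological
    replicate) shift shared by all genes (RNA input / RT efficiency), which
    reference-gene normalization must cancel; ``sigma_bio`` is gene-level
    biological noise and ``sigma_tech`` the smaller technical-replicate
    noise, all in cycles.
    """

    n_bio: int = 3
    n_tech: int = 3
    sigma_sample: float = 0.5
    sigma_bio: float = 0.25
    sigma_tech: float = 0.12
    base_ct_range: tuple[float, float] = (18.0, 28.0)
    reference_genes: tuple[str, ...] = ("PP2Acs", "clat")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bio < 1 or self.n_tech < 1:
            raise ValueError("replicate counts must be >= 1")
        for name in ("sigma_sample", "sigma_bio", "sigma_tech"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def simulate_ct_table(
    fold_changes: dict[str, dict[str, float]], params: CtSimParams
) -> pd.DataFrame:
    """Simulate a Ct table for target genes with known true folds vs Control.

    Parameters
    ----------
    fold_changes
        ``gene -> {condition -> true fold}``; Control is implicitly fold 1.
        Reference genes are added automatically with fold 1 everywhere.
    params
        :class:`CtSimParams`.

    Returns a tidy table with columns
    ``gene condition bio_rep tech_rep ct``.
    """
    for gene, conds in fold_changes.items():
        for cond, f in conds.items():
            if not f > 0:
                raise ValueError(f"fold for {gene}/{cond} must be > 0, got {f}")
    rng = np.random.default_rng(params.seed)
    genes = list(fold_changes) + [g for g in params.reference_genes if g not in fold_changes]
    base_ct = {g: rng.uniform(*params.base_ct_range) for g in genes}

    sample_shift = {
        (cond, b): rng.normal(0.0, params.sigma_sample)
        for cond in CONDITIONS
        for b in range(1, params.n_bio + 1)
    }
    rows = []
    for g in genes:
        is_ref = g in params.reference_genes
        for cond in CONDITIONS:
            fold = 1.0 if (is_ref or cond == "Control") else fold_changes[g].get(cond, 1.0)
            for b in range(1, params.n_bio + 1):
                mu = (
                    base_ct[g]
                    - math.log2(fold)
                    + sample_shift[(cond, b)]
                    + rng.normal(0.0, params.sigma_bio)
                )
                for t in range(1, params.n_tech + 1):
                    rows.append((g, cond, b, t, mu + rng.normal(0.0, params.sigma_tech)))
    return pd.DataFrame(rows, columns=["gene", "condition", "bio_rep", "tech_rep", "ct"])


def simulate_annotations(
    truth: pd.DataFrame,
    n_categories: int = 20,
    size_range: tuple[int, int] = (10, 60),
    enriched: list[dict] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a flat annotation map, optionally with designed enriched categories.

    Background categories sample proteins uniformly at random.  Each entry
    of ``enriched`` is ``{"name", "condition", "size", "direction"}``: the
    category takes the ``size`` proteins with the highest (direction
    "greater") or lowest ("smaller") true log2 fold change in ``condition``,
    so the enrich stage should flag it with that direction.

    Returns a two-column table ``protein_id  category``.
    """
    lo, hi = size_range
    if lo < 1:
        raise ValueError("category sizes must be >= 1")
    rng = np.random.default_rng(seed)
    ids = truth["protein_id"].to_numpy()
    rows: list[tuple[str, str]] = []
    for i in range(n_categories):
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(ids))
        members = rng.choice(ids, size=size, replace=False)
        rows.extend((pid, f"CAT{i:03d}") for pid in sorted(members))
    for entry in enriched or []:
        size = int(entry["size"])
        if size < 1:
            raise ValueError("enriched category size must be >= 1")
        fc = truth[f"fc_{entry['condition'].lower()}"].to_numpy()
        order = np.argsort(fc, kind="stable")
        take = order[:size] if entry.get("direction", "greater") == "smaller" else order[-size:]
        rows.extend((ids[j], entry["name"]) for j in sorted(take))
    return pd.DataFrame(rows, columns=["protein_id", "category"])
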