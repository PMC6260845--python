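"""End-to-end orchestration: simulate -> quantify -> call -> cluster -> enrich -> qPCR.

``run_all`` executes every stage in order, persists each stage's inputs and
outputs as TSV/JSON next to the report, and emits one structured
:class:`ReportBundle` whose every number is recomputable from the emitted
stage files.  Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
import yaml

from . import diffcall, enrich, io, patterns, qpcr, quantify, synth
from . import synth as _synthmod
from .design import INTENSITY_COLUMNS, TREATMENTS, DesignMap

logger = logging.getLogger("itraqpipe")

__all__ = ["PipelineConfig", "ReportBundle", "run_all", "validate_inputs"]


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run.

    Synthetic-data parameters plus every stage threshold.  ``tau = None``
    means "derive the pattern 'high' threshold from the fitted null's upper
    cutoff" (the default).
    """

    synth: _synthmod.SimParams = field(default_factory=_synthmod.SimParams)
    ct: _synthmod.CtSimParams = field(default_factory=_synthmod.CtSimParams)
    e_max: float = 0.05
    unique_only: bool = True
    min_unique: int = 2
    pairing: str = "by_replicate"
    alpha: float = 0.05
    interval: str = "2sd"
    k_clusters: int = 14
    tau: float | None = None
    min_size: int = 5
    n_categories: int = 20
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "synth" in kwargs:
            sp = dict(kwargs["synth"])
            for key in ("peptide_count_range", "channel_loading", "pattern_weights"):
                if key in sp:
                    sp[key] = tuple(sp[key])
            kwargs["synth"] = _synthmod.SimParams(**sp)
        if "ct" in kwargs:
            cp = dict(kwargs["ct"])
            for key in ("base_ct_range", "reference_genes"):
                if key in cp:
                    cp[key] = tuple(cp[key])
            kwargs["ct"] = _synthmod.CtSimParams(**cp)
        return cls(**kwargs)

    def with_seed(self, seed: int) -> "PipelineConfig":
        cfg = dataclasses.replace(self, seed=seed)
        cfg.synth = dataclasses.replace(self.synth, seed=seed)
        cfg.ct = dataclasses.replace(self.ct, seed=seed + 1)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


#: Demo-scale run: ~12,000 peptides over 2,000 proteins.
DEMO_CONFIG = {
    "synth": {"n_proteins": 2000, "peptide_count_range": [1, 11]},
}


@dataclass
class ReportBundle:
    """Structured summary of one run; serialized as ``report.json``."""

    report: dict

    def to_json(self) -> str:
        return json.dumps(self.report, indent=2, sort_keys=True)


def _stage(name: str):
    logger.info("stage: %s", name)


def run_all(config: PipelineConfig, out_dir) -> ReportBundle:
    """Run the full pipeline on synthetic data and write all artifacts to ``out_dir``."""
    out = io.ensure_dir(out_dir)
    (out / "resolved_config.json").write_text(
        json.dumps(config.to_dict(), indent=2, sort_keys=True)
    )

    _stage("synth")
    truth = synth.generate_ground_truth(config.synth)
    peptides, design = synth.simulate_peptide_table(truth, config.synth)
    annotations = synth.simulate_annotations(
        truth, n_categories=config.n_categories, seed=config.synth.seed
    )
    io.write_tsv(truth, out / "truth.tsv")
    io.write_tsv(peptides, out / "peptides.tsv")
    io.write_design(design, out / "design.tsv")
    io.write_tsv(annotations, out / "annotations.tsv")

    _stage("quantify")
    n_raw = len(peptides)
    filtered = quantify.filter_peptides(peptides, config.e_max, config.unique_only)
    logger.info("peptide filter: %d -> %d rows", n_raw, len(filtered))
    normalized, factors = quantify.normalize_channels(filtered)
    quants_all = quantify.rollup_protein(normalized)
    quants = quantify.filter_proteins(quants_all, config.min_unique)
    logger.info("protein filter: %d -> %d proteins", len(quants_all), len(quants))
    enr = quantify.compute_enrichment(quants, design, config.pairing)
    io.write_tsv(quants.reset_index(), out / "protein_quants.tsv")
    io.write_tsv(enr.reset_index().rename(columns={"index": "protein_id"}),
                 out / "enrichment.tsv")
    (out / "scale_factors.json").write_text(json.dumps(factors, indent=2, sort_keys=True))

    _stage("diffcall")
    null_sample = diffcall.replicate_ratios(quants, design)
    model = diffcall.fit_null(null_sample)
    model.to_json(out / "null_model.json")
    calls = diffcall.call_differential(enr, model, alpha=config.alpha,
                                       interval=config.interval)
    io.write_tsv(calls, out / "calls.tsv")
    venn = diffcall.partition_sets(calls)
    (out / "venn.json").write_text(
        json.dumps({"counts": venn.counts, "regions": venn.to_dict()},
                   indent=2, sort_keys=True)
    )

    _stage("patterns")
    matrix, excluded = patterns.build_matrix(calls, enr)
    pattern_counts = {p: 0 for p in (1, 2, 3, 4)}
    n_clusters = 0
    if len(matrix) >= 2:
        dend = patterns.hclust_complete(matrix)
        k = min(config.k_clusters, len(matrix))
        clusters = patterns.cut_clusters(dend, k)
        tau = config.tau if config.tau is not None else float(np.log2(model.cutoff_high))
        assignment = patterns.assign_patterns(clusters, matrix, tau=tau)
        pattern_counts = assignment.counts
        n_clusters = k
        assn = pd.DataFrame(
            {"protein_id": clusters.index, "cluster": clusters.to_numpy(),
             "pattern": assignment.protein_pattern.to_numpy()}
        )
        io.write_tsv(assn, out / "clusters.tsv")
        io.write_tsv(assignment.centroids.reset_index(), out / "centroids.tsv")
        io.write_tsv(dend.merge_table(), out / "dendrogram.tsv")
        (out / "dendrogram.nwk").write_text(patterns.to_newick(dend) + "\n")
    else:
        logger.warning("fewer than 2 differential proteins; clustering skipped")

    _stage("enrich")
    enrich_summary = {}
    for cond in TREATMENTS:
        with np.errstate(invalid="ignore", divide="ignore"):
            ratios = pd.Series(
                np.log2(enr[cond.lower()].to_numpy(dtype=float)), index=enr.index
            )
        res = enrich.enrich_categories(
            ratios, annotations, condition=cond, min_size=config.min_size,
            alpha=config.alpha,
        )
        io.write_tsv(res, out / f"enrichment_categories_{cond.lower()}.tsv")
        enrich_summary[cond] = int(res["significant"].sum())

    _stage("qpcr")
    targets = _pick_qpcr_targets(truth)
    fold_spec = {
        gene: {cond: float(2.0 ** truth.loc[truth.protein_id == pid, f"fc_{cond.lower()}"].iloc[0])
               for cond in TREATMENTS}
        for gene, pid in targets.items()
    }
    ct_table = synth.simulate_ct_table(fold_spec, config.ct)
    io.write_tsv(ct_table, out / "ct.tsv")
    folds = qpcr.livak_table(ct_table, config.ct.reference_genes, alpha=config.alpha)
    io.write_tsv(folds, out / "qpcr_folds.tsv")
    conc = qpcr.concordance(calls, folds, targets)
    io.write_tsv(conc, out / "concordance.tsv")

    per_cond = {
        cond: int(((calls["condition"] == cond) & calls["significant"]).sum())
        for cond in TREATMENTS
    }
    report = {
        "provenance": {
            "seed": config.seed,
            "config_sha256": hashlib.sha256(
                json.dumps(config.to_dict(), sort_keys=True).encode()
            ).hexdigest(),
        },
        "counts": {
            "peptides_raw": n_raw,
            "peptides_used": int(len(filtered)),
            "proteins_quantified": int(len(quants_all)),
            "proteins_min_unique": int(len(quants)),
        },
        "null_model": model.to_dict(),
        "differential": per_cond,
        "venn": venn.counts,
        "patterns": {str(k): v for k, v in pattern_counts.items()},
        "n_clusters": n_clusters,
        "clustered_proteins": int(len(matrix)),
        "excluded_from_matrix": len(excluded),
        "enriched_categories": enrich_summary,
        "qpcr": {
            "genes": sorted(targets),
            "concordant": int(conc["concordant"].sum()),
            "pairs": int(len(conc)),
        },
    }
    bundle = ReportBundle(report)
    (out / "report.json").write_text(bundle.to_json())
    return bundle


def _pick_qpcr_targets(truth: pd.DataFrame) -> dict[str, str]:
    """One qPCR target per pattern archetype present (first protein of each)."""
    targets = {}
    for p in ("1", "2", "3", "4"):
        sub = truth.loc[truth["pattern"] == p, "protein_id"]
        if len(sub):
            targets[f"gene_p{p}"] = str(sub.iloc[0])
    return targets


def validate_inputs(files: dict[str, str]) -> list[str]:
    """Schema-check input TSVs; returns line-numbered issue strings (never raises).

    ``files`` maps kind -> path for any of: ``peptides``, ``design``,
    ``annotations``, ``ct``.
    """
    issues: list[str] = []
    if "design" in files:
        try:
            io.read_design(files["design"])
        except Exception as exc:  # noqa: BLE001 - collecting, not handling
            issues.append(f"design: {exc}")
    if "peptides" in files:
        try:
            table = pd.read_csv(files["peptides"], sep="\t")
            missing = [c for c in io.PEPTIDE_COLUMNS if c not in table.columns]
            if missing:
                issues.append(f"peptides: missing columns {missing}")
            else:
                for col in INTENSITY_COLUMNS:
                    bad = table.index[table[col] < 0]
                    issues.extend(
                        f"peptides line {i + 2}: negative intensity in {col}" for i in bad
                    )
                bad = table.index[table["expect_value"] < 0]
                issues.extend(
                    f"peptides line {i + 2}: negative expect_value" for i in bad
                )
                no_signal = table.index[table[list(INTENSITY_COLUMNS)].isna().all(axis=1)]
                issues.extend(
                    f"peptides line {i + 2}: all intensities missing" for i in no_signal
                )
        except Exception as exc:  # noqa: BLE001
            issues.append(f"peptides: {exc}")
    if "annotations" in files:
        try:
            io.read_annotations(files["annotations"])
        except Exception as exc:  # noqa: BLE001
            issues.append(f"annotations: {exc}")
    if "ct" in files:
        try:
            table = io.read_ct(files["ct"])
            odd = table.index[(table["ct"] < 5) | (table["ct"] > 40)]
            issues.extend(f"ct line {i + 2}: Ct outside (5, 40)" for i in odd)
        except Exception as exc:  # noqa: BLE001
            issues.append(f"ct: {exc}")
    return issues
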