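"""TSV readers/writers for the pipeline's tabular interchange formats.

All on-disk formats are plain tab-separated text.  Missing reporter
intensities are blank fields.  Floats are written with ``%.10g`` so that a
fixed input always serializes to identical bytes.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .design import INTENSITY_COLUMNS, DesignMap

FLOAT_FORMAT = "%.10g"

PEPTIDE_COLUMNS = ["protein_id", "peptide_seq", "is_unique", "expect_value", *INTENSITY_COLUMNS]
CT_COLUMNS = ["gene", "condition", "bio_rep", "tech_rep", "ct"]


def write_tsv(frame: pd.DataFrame, path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT, na_rep="")


def read_peptides(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "peptide_seq": str})
    missing = [c for c in PEPTIDE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"peptide table {path} lacks columns {missing}")
    table["is_unique"] = table["is_unique"].astype(bool)
    return table


def read_design(path) -> DesignMap:
    return DesignMap.from_frame(pd.read_csv(path, sep="\t", dtype={"channel": str}))


def write_design(design: DesignMap, path) -> None:
    write_tsv(design.to_frame(), path)


def read_ct(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"gene": str, "condition": str})
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table {path} lacks columns {missing}")
    return table


def read_annotations(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("protein_id", "category") if c not in table.columns]
    if missing:
        raise ValueError(f"annotation table {path} lacks columns {missing}")
    return table


def read_quants(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"protein_id": str}).set_index("protein_id")


def read_enrichment(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"protein_id": str}).set_index("protein_id")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
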