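import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from itraqpipe import diffcall, quantify, synth
from itraqpipe.design import INTENSITY_COLUMNS, DesignMap

settings.register_profile(
    "suite",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def quantify_chain(params, e_max=0.05, unique_only=True, min_unique=2):
    """Generator -> filtered/normalized/rolled-up quants + enrichment, for tests."""
    truth = synth.generate_ground_truth(params)
    peptides, design = synth.simulate_peptide_table(truth, params)
    filtered = quantify.filter_peptides(peptides, e_max, unique_only)
    normalized, _ = quantify.normalize_channels(filtered)
    quants = quantify.filter_proteins(quantify.rollup_protein(normalized), min_unique)
    enr = quantify.compute_enrichment(quants, design)
    return truth, quants, enr, design


def random_peptide_table(rng, n_proteins=8, max_peptides=5, missing_frac=0.1):
    """Small random peptide-evidence table with some missing intensities."""
    rows = []
    pep = 0
    for i in range(n_proteins):
        for _ in range(rng.integers(1, max_peptides + 1)):
            intens = rng.uniform(1e3, 1e6, size=len(INTENSITY_COLUMNS))
            mask = rng.random(len(intens)) < missing_frac
            intens[mask] = np.nan
            if mask.all():
                intens[0] = rng.uniform(1e3, 1e6)
            rows.append(
                {
                    "protein_id": f"P{i:03d}",
                    "peptide_seq": f"PEPTIDE{pep}",
                    "is_unique": bool(rng.random() > 0.2),
                    "expect_value": float(rng.uniform(0, 0.1)),
                    **dict(zip(INTENSITY_COLUMNS, intens)),
                }
            )
            pep += 1
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def design():
    return DesignMap.default()


@pytest.fixture
def null_model_061_161():
    """Null whose 2-SD cutoffs sit near the (0.61, 1.61) fold-change scale."""
    rng = np.random.default_rng(7)
    x = rng.normal(0.0, 1.0, size=4001)
    x = (x - x.mean()) / x.std() * (np.log2(1.61) / 2.0)  # exact mu=0, sigma=tau/2
    return diffcall.fit_null(2.0**x)
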