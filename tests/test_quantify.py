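"""Quantification chain: filters, normalization, rollup, enrichment ratios."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import oracles
from conftest import quantify_chain, random_peptide_table
from itraqpipe import quantify, synth
from itraqpipe.design import INTENSITY_COLUMNS, TREATMENTS, DesignMap


def peptide_row(protein="P1", seq="AAA", unique=True, expect=0.01, intensities=None):
    intensities = intensities if intensities is not None else [100.0] * 8
    return {"protein_id": protein, "peptide_seq": seq, "is_unique": unique,
            "expect_value": expect, **dict(zip(INTENSITY_COLUMNS, intensities))}


class TestFilterPeptides:
    def test_boundary_is_strict(self):
        table = pd.DataFrame([peptide_row(expect=0.05), peptide_row(expect=0.049999)])
        out = quantify.filter_peptides(table)
        assert len(out) == 1 and out.iloc[0]["expect_value"] < 0.05

    def test_all_passing_rows_are_kept_in_order(self):
        table = pd.DataFrame([peptide_row(seq=f"S{i}", expect=0.01) for i in range(5)])
        out = quantify.filter_peptides(table)
        assert list(out["peptide_seq"]) == [f"S{i}" for i in range(5)]

    def test_unique_flag_filter(self):
        table = pd.DataFrame([peptide_row(unique=False), peptide_row(seq="BBB")])
        assert len(quantify.filter_peptides(table, unique_only=True)) == 1
        assert len(quantify.filter_peptides(table, unique_only=False)) == 2

    @given(st.lists(st.floats(0.0, 0.2), min_size=1, max_size=40))
    def test_matches_row_by_row_oracle(self, evalues):
        table = pd.DataFrame([peptide_row(seq=f"S{i}", expect=e)
                              for i, e in enumerate(evalues)])
        out = quantify.filter_peptides(table, unique_only=False)
        assert len(out) == sum(e < 0.05 for e in evalues)


class TestNormalizeChannels:
    def test_equal_sums_give_unit_factors(self):
        table = pd.DataFrame([peptide_row(), peptide_row(seq="BBB")])
        out, factors = quantify.normalize_channels(table)
        assert all(f == pytest.approx(1.0) for f in factors.values())
        assert np.allclose(out[list(INTENSITY_COLUMNS)], table[list(INTENSITY_COLUMNS)])

    def test_doubled_channel_normalizes_back(self, rng):
        table, _ = quantify.normalize_channels(random_peptide_table(rng, missing_frac=0.0))
        doubled = table.copy()
        doubled[INTENSITY_COLUMNS[2]] *= 2.0
        out, factors = quantify.normalize_channels(doubled)
        # the doubled channel is scaled back down by half relative to the others
        rel = factors[INTENSITY_COLUMNS[2][1:]] / factors[INTENSITY_COLUMNS[0][1:]]
        assert rel == pytest.approx(0.5)
        ratio_out = out[INTENSITY_COLUMNS[2]] / out[INTENSITY_COLUMNS[0]]
        ratio_in = table[INTENSITY_COLUMNS[2]] / table[INTENSITY_COLUMNS[0]]
        assert np.allclose(ratio_out, ratio_in)

    def test_channel_sums_equal_grand_mean_afterwards(self, rng):
        table = random_peptide_table(rng)
        pre = oracles.naive_channel_sums(table, INTENSITY_COLUMNS)
        out, _ = quantify.normalize_channels(table)
        post = oracles.naive_channel_sums(out, INTENSITY_COLUMNS)
        grand = np.mean(list(pre.values()))
        for c in INTENSITY_COLUMNS:
            assert post[c] == pytest.approx(grand, rel=1e-9)

    def test_idempotent(self, rng):
        table = random_peptide_table(rng)
        once, _ = quantify.normalize_channels(table)
        twice, factors = quantify.normalize_channels(once)
        assert all(abs(f - 1.0) < 1e-9 for f in factors.values())

    def test_dead_channel_is_named(self):
        table = pd.DataFrame([peptide_row()])
        table[INTENSITY_COLUMNS[3]] = np.nan
        with pytest.raises(quantify.NormalizationError, match="116"):
            quantify.normalize_channels(table)

    def test_preserves_within_channel_ratios(self, rng):
        """Only per-channel scaling: the ratio between two rows of the same
        channel is untouched."""
        table = random_peptide_table(rng, missing_frac=0.0)
        out, _ = quantify.normalize_channels(table)
        c = INTENSITY_COLUMNS[5]
        assert np.allclose(out[c].iloc[1:].to_numpy() / out[c].iloc[0],
                           table[c].iloc[1:].to_numpy() / table[c].iloc[0])


class TestRollup:
    def test_single_peptide_protein_keeps_its_ratios(self):
        intens = [100, 200, 300, 400, 500, 600, 700, 800]
        table = pd.DataFrame([peptide_row(intensities=intens)])
        q = quantify.rollup_protein(table)
        got = q.loc["P1", list(INTENSITY_COLUMNS)].to_numpy(dtype=float)
        assert np.allclose(got / got[0], np.array(intens) / intens[0])

    def test_hand_summation_example(self):
        # intensities (100, 300) and (200, 300) in two channels -> 400/500
        t = pd.DataFrame([
            peptide_row(seq="A", intensities=[100, 200] + [np.nan] * 6),
            peptide_row(seq="B", intensities=[300, 300] + [np.nan] * 6),
        ])
        q = quantify.rollup_protein(t)
        a = q.loc["P1", INTENSITY_COLUMNS[0]]
        b = q.loc["P1", INTENSITY_COLUMNS[1]]
        assert a / b == pytest.approx(400 / 500)

    def test_missing_channel_is_flagged_missing(self):
        t = pd.DataFrame([peptide_row(intensities=[100] * 7 + [np.nan])])
        q = quantify.rollup_protein(t)
        assert np.isnan(q.loc["P1", INTENSITY_COLUMNS[7]])

    def test_matches_double_loop_oracle(self, rng):
        table = random_peptide_table(rng, n_proteins=12)
        q = quantify.rollup_protein(table)
        expected = oracles.naive_rollup(table, INTENSITY_COLUMNS)
        assert set(q.index) == set(expected)
        for pid, acc in expected.items():
            for c in INTENSITY_COLUMNS:
                got = q.loc[pid, c]
                want = acc[c]
                assert (np.isnan(got) and np.isnan(want)) or got == pytest.approx(want)

    def test_unique_peptide_count(self):
        t = pd.DataFrame([
            peptide_row(seq="A", unique=True),
            peptide_row(seq="A", unique=True),   # same sequence counted once
            peptide_row(seq="B", unique=False),
            peptide_row(seq="C", unique=True),
        ])
        q = quantify.rollup_protein(t)
        assert q.loc["P1", "n_unique_peptides"] == 2
        assert q.loc["P1", "n_peptides_used"] == 4


class TestFilterProteins:
    def test_boundaries(self):
        q = pd.DataFrame(
            {"n_unique_peptides": [1, 2, 5]},
            index=pd.Index(["A", "B", "C"], name="protein_id"),
        )
        kept = quantify.filter_proteins(q, min_unique=2)
        assert list(kept.index) == ["B", "C"]

    def test_one_unique_among_shared_is_removed(self):
        t = pd.DataFrame(
            [peptide_row(seq="U", unique=True)]
            + [peptide_row(seq=f"S{i}", unique=False) for i in range(5)]
        )
        q = quantify.rollup_protein(t)
        assert len(quantify.filter_proteins(q, min_unique=2)) == 0

    def test_matches_brute_force(self, rng):
        n = rng.integers(0, 8, size=30)
        q = pd.DataFrame({"n_unique_peptides": n},
                         index=pd.Index([f"P{i}" for i in range(30)], name="protein_id"))
        kept = quantify.filter_proteins(q, min_unique=3)
        assert set(kept.index) == {f"P{i}" for i in range(30) if n[i] >= 3}


class TestEnrichment:
    def quants(self, values):
        return pd.DataFrame([values], columns=list(INTENSITY_COLUMNS),
                            index=pd.Index(["P1"], name="protein_id"))

    def test_flat_abundances_give_unit_ratios(self, design):
        enr = quantify.compute_enrichment(self.quants([5.0] * 8), design)
        assert np.allclose(enr.loc["P1"], 1.0)

    def test_doubled_condition_gives_ratio_two(self, design):
        v = [1.0] * 8
        for rep in (1, 2):
            v[list(INTENSITY_COLUMNS).index(f"i{design.channel('Burned', rep)}")] = 2.0
        enr = quantify.compute_enrichment(self.quants(v), design)
        assert enr.loc["P1", "burned"] == pytest.approx(2.0)
        assert enr.loc["P1", "limit"] == pytest.approx(1.0)

    def test_matches_elementwise_division(self, rng, design):
        vals = rng.uniform(1, 100, size=(20, 8))
        quants = pd.DataFrame(vals, columns=list(INTENSITY_COLUMNS),
                              index=pd.Index([f"P{i}" for i in range(20)],
                                             name="protein_id"))
        enr = quantify.compute_enrichment(quants, design)
        for cond in TREATMENTS:
            for rep in (1, 2):
                t = quants[f"i{design.channel(cond, rep)}"]
                c = quants[f"i{design.channel('Control', rep)}"]
                assert np.allclose(enr[f"{cond.lower()}_r{rep}"], t / c)
            r1 = enr[f"{cond.lower()}_r1"]
            r2 = enr[f"{cond.lower()}_r2"]
            assert np.allclose(enr[cond.lower()], np.sqrt(r1 * r2))

    def test_missing_control_yields_missing_cell(self, design):
        v = [np.nan if c == f"i{design.channel('Control', 1)}" else 4.0
             for c in INTENSITY_COLUMNS]
        enr = quantify.compute_enrichment(self.quants(v), design)
        assert np.isnan(enr.loc["P1", "burned_r1"])
        # summary falls back to the surviving replicate
        assert enr.loc["P1", "burned"] == pytest.approx(1.0)

    def test_protein_scale_invariance(self, rng, design):
        """Scaling every intensity of one protein leaves its ratios unchanged."""
        vals = rng.uniform(1, 100, size=(5, 8))
        quants = pd.DataFrame(vals, columns=list(INTENSITY_COLUMNS),
                              index=pd.Index([f"P{i}" for i in range(5)],
                                             name="protein_id"))
        scaled = quants.copy()
        scaled.loc["P2"] *= 37.5
        a = quantify.compute_enrichment(quants, design)
        b = quantify.compute_enrichment(scaled, design)
        assert np.allclose(a.loc["P2"], b.loc["P2"])

    def test_by_control_mean_pairing(self, rng, design):
        vals = rng.uniform(1, 100, size=(6, 8))
        quants = pd.DataFrame(vals, columns=list(INTENSITY_COLUMNS),
                              index=pd.Index([f"P{i}" for i in range(6)],
                                             name="protein_id"))
        enr = quantify.compute_enrichment(quants, design, pairing="by_control_mean")
        gm = np.sqrt(quants[f"i{design.channel('Control', 1)}"]
                     * quants[f"i{design.channel('Control', 2)}"])
        t = quants[f"i{design.channel('Limit', 2)}"]
        assert np.allclose(enr["limit_r2"], t / gm)


class TestEndToEndRecovery:
    def test_zero_noise_null_ratios_are_exactly_one(self):
        params = synth.SimParams(
            n_proteins=40, sigma_noise=0.0, sigma_rep=0.0, frac_null=1.0,
            missing_intensity_threshold=0.0, seed=21,
        )
        _, _, enr, _ = quantify_chain(params)
        assert np.allclose(enr.to_numpy(dtype=float), 1.0, atol=1e-9)

    def test_zero_noise_effects_recovered_exactly_without_normalization(self):
        """With zero noise and equal loading the rollup/enrichment chain
        returns 2**FC exactly.  (Global normalization is skipped here: it
        rescales whole channels and is only ratio-faithful when most
        proteins are unchanged.)"""
        params = synth.SimParams(
            n_proteins=40, sigma_noise=0.0, sigma_rep=0.0, frac_null=0.5,
            channel_loading=(1.0,) * 8, missing_intensity_threshold=0.0, seed=22,
        )
        truth = synth.generate_ground_truth(params)
        peptides, design = synth.simulate_peptide_table(truth, params)
        quants = quantify.rollup_protein(quantify.filter_peptides(peptides))
        enr = quantify.compute_enrichment(quants, design)
        t = truth.set_index("protein_id").loc[enr.index]
        for cond in TREATMENTS:
            assert np.allclose(enr[cond.lower()],
                               2.0 ** t[f"fc_{cond.lower()}"], atol=1e-9)

    def test_default_noise_rollup_recovers_fold_changes(self):
        """Monte-Carlo: across seeds, the log2 error of recovered fold
        changes is far below the per-peptide noise level."""
        errs = []
        for seed in range(5):
            params = synth.SimParams(n_proteins=300, seed=seed)
            truth, quants, enr, _ = quantify_chain(params)
            t = truth.set_index("protein_id").loc[enr.index]
            for cond in TREATMENTS:
                err = np.log2(enr[cond.lower()]) - t[f"fc_{cond.lower()}"]
                errs.append(np.sqrt(np.mean(err**2)))
        # replicate noise (sigma_rep = 0.3) dominates; reporter noise is averaged out
        assert np.mean(errs) < 3 * 0.3
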