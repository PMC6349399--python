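"""Tests of orientation correction, normalization, and protein roll-up."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from silacq.quant import (
    apply_design,
    merge_replicates,
    normalize_ratios,
    peptide_log_ratios,
    summarize_protein,
)
from silacq.synthetic import SimulationConfig, generate_gene_truth, generate_psm_table
from silacq.psm import DEFAULT_COLUMN_MAP

from conftest import make_psm_frame


def ratios_frame(rows):
    """(gene, replicate, log2_ratio) tuples -> PeptideRatio frame."""
    return pd.DataFrame(
        rows, columns=["gene_id", "replicate_id", "log2_ratio"]
    )


class TestPeptideLogRatios:
    @pytest.mark.parametrize(
        "hl,orientation,expected",
        [(2.0, "forward", 1.0), (2.0, "swap", -1.0), (1.0, "forward", 0.0)],
    )
    def test_orientation_convention(self, hl, orientation, expected):
        psms = make_psm_frame([("G", set(), hl, "r1")])
        psms["orientation"] = orientation
        out = peptide_log_ratios(psms)
        assert out.loc[0, "log2_ratio"] == pytest.approx(expected)

    def test_nonpositive_ratio_rejected(self):
        psms = make_psm_frame([("G", set(), -1.0, "r1")])
        psms["orientation"] = "forward"
        with pytest.raises(ValueError, match="positive"):
            peptide_log_ratios(psms)

    def test_orientation_required(self):
        psms = make_psm_frame([("G", set(), 2.0, "r1")])
        with pytest.raises(ValueError, match="orientation"):
            peptide_log_ratios(psms)

    def test_apply_design_attaches_orientation(self):
        psms = make_psm_frame(
            [("G", set(), 2.0, "r1"), ("G", set(), 2.0, "r2")]
        )
        design = pd.DataFrame(
            {"replicate_id": ["r1", "r2"], "orientation": ["forward", "swap"]}
        )
        out = peptide_log_ratios(apply_design(psms, design))
        assert list(out["log2_ratio"]) == [1.0, -1.0]

    def test_apply_design_missing_replicate(self):
        psms = make_psm_frame([("G", set(), 2.0, "r9")])
        design = pd.DataFrame(
            {"replicate_id": ["r1"], "orientation": ["forward"]}
        )
        with pytest.raises(ValueError, match="r9"):
            apply_design(psms, design)


class TestNormalizeRatios:
    def test_already_centered_unchanged(self):
        table = ratios_frame(
            [("A", "r1", -0.5), ("B", "r1", 0.0), ("C", "r1", 0.5)]
        )
        out = normalize_ratios(table)
        np.testing.assert_allclose(out["log2_ratio"], [-0.5, 0.0, 0.5])

    def test_median_centering(self):
        table = ratios_frame(
            [("A", "r1", 0.5), ("B", "r1", 1.0), ("C", "r1", 1.5)]
        )
        out = normalize_ratios(table)
        np.testing.assert_allclose(out["log2_ratio"], [-0.5, 0.0, 0.5])

    def test_none_is_identity(self):
        table = ratios_frame([("A", "r1", 0.7)])
        out = normalize_ratios(table, method="none")
        pd.testing.assert_frame_equal(out, table)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            normalize_ratios(ratios_frame([]))

    @given(
        values=st.lists(
            st.floats(-10, 10, allow_nan=False), min_size=1, max_size=30
        ),
        values2=st.lists(
            st.floats(-10, 10, allow_nan=False), min_size=1, max_size=30
        ),
    )
    @settings(max_examples=50, deadline=None)
    def test_per_replicate_median_is_zero(self, values, values2):
        rows = [("G", "r1", v) for v in values]
        rows += [("G", "r2", v) for v in values2]
        out = normalize_ratios(ratios_frame(rows))
        for _, group in out.groupby("replicate_id"):
            assert abs(group["log2_ratio"].median()) < 1e-12


class TestSummarizeProtein:
    def test_odd_count_median(self):
        table = ratios_frame(
            [("G", "r1", 1.0), ("G", "r1", 1.2), ("G", "r1", 3.0)]
        )
        out = summarize_protein(table)
        assert out.loc[0, "log2fc"] == 1.2
        assert out.loc[0, "n_peptides"] == 3

    def test_even_count_midpoint(self):
        table = ratios_frame([("G", "r1", 1.0), ("G", "r1", 3.0)])
        out = summarize_protein(table)
        assert out.loc[0, "log2fc"] == 2.0

    def test_direction_of_shifted_vs_centered_genes(self):
        rng = np.random.default_rng(1)
        rows = [("ZSCAN4-like", "r1", v) for v in rng.normal(4, 0.5, 20)]
        rows += [("RPL15-like", "r1", v) for v in rng.normal(0, 0.5, 20)]
        out = summarize_protein(ratios_frame(rows)).set_index("gene_id")
        assert out.loc["ZSCAN4-like", "log2fc"] > 2
        assert abs(out.loc["RPL15-like", "log2fc"]) < 0.5

    @given(
        st.lists(
            st.floats(-20, 20, allow_nan=False), min_size=1, max_size=25
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_median_matches_sort_oracle(self, values):
        table = ratios_frame([("G", "r1", v) for v in values])
        out = summarize_protein(table)
        s = sorted(values)
        n = len(s)
        oracle = (
            s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2.0
        )
        assert out.loc[0, "log2fc"] == oracle


class TestMergeReplicates:
    def per_rep(self, rows):
        return pd.DataFrame(
            rows,
            columns=["gene_id", "replicate_id", "log2fc", "n_peptides"],
        )

    def test_mislabeled_gene_pulled_toward_zero(self):
        table = self.per_rep(
            [("G", "r1", 2.0, 3), ("G", "r2", 0.0, 3)]
        )
        merged, _ = merge_replicates(table)
        assert merged.loc[0, "merged_log2fc"] == 1.0

    def test_single_replicate_gene_dropped(self):
        table = self.per_rep(
            [
                ("A", "r1", 2.0, 3),
                ("A", "r2", 2.2, 3),
                ("B", "r1", 1.0, 5),
            ]
        )
        merged, excluded = merge_replicates(table)
        assert list(merged["gene_id"]) == ["A"]
        assert list(excluded["gene_id"]) == ["B"]
        assert excluded.loc[0, "exclusion_reason"] == "too_few_replicates"

    def test_single_peptide_gene_in_side_report_with_estimate(self):
        # a gene seen in both replicates but via one peptide total per
        # replicate short of the peptide floor keeps its estimate in the
        # side table (min_peptides_total=3 here to force exclusion)
        table = self.per_rep(
            [("SMG6-like", "r1", -4.7, 1), ("SMG6-like", "r2", -4.7, 1)]
        )
        merged, excluded = merge_replicates(table, min_peptides_total=3)
        assert merged.empty
        assert excluded.loc[0, "exclusion_reason"] == "too_few_peptides"
        assert excluded.loc[0, "merged_log2fc"] == -4.7

    def test_min_replicates_exceeding_design_is_error(self):
        table = self.per_rep([("A", "r1", 1.0, 2)])
        with pytest.raises(ValueError, match="min_replicates"):
            merge_replicates(table, min_replicates=2, design_replicates=["r1"])

    def test_single_replicate_design_supported(self):
        table = self.per_rep([("A", "r1", 1.0, 2)])
        merged, _ = merge_replicates(
            table, min_replicates=1, design_replicates=["r1"]
        )
        assert merged.loc[0, "merged_log2fc"] == 1.0

    def test_peptide_total_is_sum_over_replicates(self):
        table = self.per_rep(
            [("A", "r1", 1.0, 2), ("A", "r2", 1.0, 5)]
        )
        merged, _ = merge_replicates(table)
        assert merged.loc[0, "n_peptides_total"] == 7


def simulate_per_replicate(mislabel_fraction, seed=0, n_genes=800):
    cfg = SimulationConfig(
        n_genes=n_genes, mislabel_fraction=mislabel_fraction,
        flag_fraction=0.0, seed=seed,
    )
    truth = generate_gene_truth(cfg)
    psms = generate_psm_table(truth, cfg)
    psms = psms.rename(
        columns={v: k for k, v in DEFAULT_COLUMN_MAP.items()}
    ).rename(columns={"ratio": "hl_ratio"})
    design = pd.DataFrame(
        {"replicate_id": ["rep1", "rep2"], "orientation": ["forward", "swap"]}
    )
    ratios = normalize_ratios(peptide_log_ratios(apply_design(psms, design)))
    return truth, summarize_protein(ratios)


class TestLabelSwapBehaviour:
    def test_merged_magnitude_bounded_by_largest_replicate(self):
        truth, per_rep = simulate_per_replicate(0.05, seed=2)
        merged, _ = merge_replicates(per_rep)
        mislabeled = set(truth.loc[truth["mislabeled"], "gene_id"])
        per_gene_max = (
            per_rep.groupby("gene_id")["log2fc"].apply(
                lambda s: s.abs().max()
            )
        )
        check = merged[merged["gene_id"].isin(mislabeled)]
        assert len(check) > 0
        for _, row in check.iterrows():
            assert abs(row["merged_log2fc"]) <= per_gene_max[
                row["gene_id"]
            ] + 1e-12

    def test_replicate_correlation_decreases_with_mislabeling(self):
        correlations = []
        for fraction in (0.0, 0.05, 0.2):
            _, per_rep = simulate_per_replicate(fraction, seed=4)
            wide = per_rep.pivot(
                index="gene_id", columns="replicate_id", values="log2fc"
            ).dropna()
            correlations.append(wide["rep1"].corr(wide["rep2"]))
        assert correlations[0] > correlations[1] > correlations[2]
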