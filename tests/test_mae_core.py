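"""SNP classification bands, MAE frequency statistic, cohort summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maescan import datasets
from maescan.mae_core import (
    DaeBands,
    baf_histogram,
    classify_baf,
    cohort_summary,
    group_compare,
    mae_frequency,
)


def band_oracle(baf, tau=0.05, lo=0.35, hi=0.65):
    """Direct interval-definition oracle for the three-way classification."""
    if baf <= tau or baf >= 1 - tau:
        return "CompleteMAE"
    if baf <= lo or baf >= hi:
        return "SkewedDAE"
    return "BiallelicBalanced"


class TestClassification:
    @pytest.mark.parametrize(
        "baf,expected",
        [(1.0, "CompleteMAE"), (0.0, "CompleteMAE"), (0.5, "BiallelicBalanced"),
         (0.30, "SkewedDAE"), (0.70, "SkewedDAE")],
    )
    def test_examples(self, baf, expected):
        assert classify_baf(baf) == expected

    def test_grid_matches_interval_oracle(self):
        grid = np.round(np.arange(0, 101) / 100, 2)
        got = classify_baf(grid)
        assert list(got) == [band_oracle(b) for b in grid]

    def test_invalid_bands_rejected(self):
        with pytest.raises(ValueError):
            DaeBands(complete_tau=0.4, skew_lo=0.35, skew_hi=0.65)


def snp_table(sample_states, chrom="1"):
    rows = []
    for sample, states in sample_states.items():
        for i, hom in enumerate(states):
            rows.append(
                {
                    "sample_id": sample,
                    "chrom": chrom,
                    "pos": 1000 * (i + 1),
                    "baf": 0.0 if hom else 0.5,
                    "rna_call": "HomA" if hom else "Het",
                }
            )
    return pd.DataFrame(rows)


class TestMaeFrequency:
    @pytest.mark.parametrize(
        "n_hom,n_total,expected",
        [(60, 100, 0.60), (0, 500, 0.0), (3, 4, 0.75)],
    )
    def test_ratio(self, n_hom, n_total, expected):
        table = snp_table({"S1": [True] * n_hom + [False] * (n_total - n_hom)})
        out = mae_frequency(table)
        assert out.loc[0, "n_informative"] == n_total
        assert out.loc[0, "mae_frequency"] == pytest.approx(expected, abs=1e-9)

    def test_zero_informative_warns_not_crashes(self, caplog):
        table = snp_table({"S1": [True] * 3}, chrom="X")
        out = mae_frequency(table)  # all SNPs on X, autosomal count is 0
        assert np.isnan(out.loc[0, "mae_frequency"])
        assert out.loc[0, "mae_frequency_x"] == 1.0

    def test_x_excluded_from_headline_by_default(self):
        auto = snp_table({"S1": [True, False]})
        x = snp_table({"S1": [True, True]}, chrom="X")
        out = mae_frequency(pd.concat([auto, x], ignore_index=True))
        assert out.loc[0, "mae_frequency"] == 0.5
        assert out.loc[0, "mae_frequency_x"] == 1.0
        both = mae_frequency(pd.concat([auto, x], ignore_index=True), include_x=True)
        assert both.loc[0, "mae_frequency"] == 0.75

    def test_order_and_relabel_invariance(self):
        table = snp_table({"S1": [True, False, True, False, False]})
        shuffled = table.sample(frac=1.0, random_state=3).reset_index(drop=True)
        relabeled = table.copy()
        relabeled["rna_call"] = relabeled["rna_call"].map(
            {"HomA": "HomB", "HomB": "HomA", "Het": "Het"}
        )
        f = lambda t: mae_frequency(t).loc[0, "mae_frequency"]
        assert f(table) == f(shuffled) == f(relabeled)

    @given(st.lists(st.booleans(), min_size=1, max_size=60))
    @settings(max_examples=60, derandomize=True)
    def test_monotonicity_under_appending(self, states):
        base = snp_table({"S1": states})
        f0 = mae_frequency(base).loc[0, "mae_frequency"]
        plus_bal = snp_table({"S1": states + [False]})
        plus_mae = snp_table({"S1": states + [True]})
        if f0 > 0:
            assert mae_frequency(plus_bal).loc[0, "mae_frequency"] < f0
        if f0 < 1:
            assert mae_frequency(plus_mae).loc[0, "mae_frequency"] > f0


class TestCohortSummary:
    def test_published_imputed_column(self):
        s = datasets.sample_summaries("imputed")
        out = cohort_summary(s)
        assert round(out["mean"], 2) == 0.60
        assert round(out["sd"], 2) == 0.21
        assert out["min"] == pytest.approx(0.28)
        assert out["max"] == pytest.approx(0.80)

    def test_published_non_imputed_range(self):
        out = cohort_summary(datasets.sample_summaries("non-imputed"))
        assert out["min"] == pytest.approx(0.17)
        assert out["max"] == pytest.approx(0.77)
        assert round(out["sd"], 2) == 0.24  # n-1 denominator

    def test_degenerate_identical_values(self):
        out = cohort_summary([0.5] * 5)
        assert out["mean"] == 0.5 and out["sd"] == 0.0

    def test_single_sample_has_no_sd(self):
        assert cohort_summary([0.3])["sd"] is None

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30))
    @settings(max_examples=60, derandomize=True)
    def test_mean_within_range_and_sd_nonnegative(self, values):
        out = cohort_summary(values)
        assert out["min"] - 1e-12 <= out["mean"] <= out["max"] + 1e-12
        assert out["sd"] >= 0.0
        if len(set(values)) == 1:
            assert out["sd"] == 0.0


class TestGroupCompare:
    def test_published_nras_group_sd(self):
        out = group_compare(datasets.sample_summaries("non-imputed"))
        assert round(out["groups"]["NRAS"]["sd"], 2) == 0.18
        assert round(out["groups"]["NRAS"]["mean"], 2) == 0.59
        # Welch test is non-significant, matching the published conclusion
        assert out["p_value"] == pytest.approx(0.70, abs=0.01)

    def test_identical_groups_p_one(self):
        s = pd.DataFrame(
            {
                "mutational_status": ["A"] * 3 + ["B"] * 3,
                "mae_frequency": [0.2, 0.5, 0.8] * 2,
            }
        )
        out = group_compare(s, groups=("A", "B"))
        assert out["p_value"] == pytest.approx(1.0)

    def test_fully_separated_groups(self):
        s = pd.DataFrame(
            {
                "mutational_status": ["A"] * 3 + ["B"] * 3,
                "mae_frequency": [0.0] * 3 + [1.0] * 3,
            }
        )
        out = group_compare(s, groups=("A", "B"))
        assert out["groups"]["A"]["mean"] == 0.0
        assert out["groups"]["B"]["mean"] == 1.0

    def test_empty_group_is_an_error(self):
        s = pd.DataFrame({"mutational_status": ["A"], "mae_frequency": [0.5]})
        with pytest.raises(ValueError, match="'B'"):
            group_compare(s, groups=("A", "B"))


class TestBafHistogram:
    def test_all_mass_in_first_bin(self):
        counts, edges = baf_histogram(np.zeros(10), n_bins=10)
        assert counts[0] == 10 and counts[1:].sum() == 0

    def test_counts_conserved_and_last_bin_closed(self):
        rng = np.random.default_rng(0)
        values = np.concatenate([rng.random(500), [1.0, 1.0]])
        counts, edges = baf_histogram(values, n_bins=20)
        assert counts.sum() == len(values)
        assert counts[-1] >= 2

    def test_bimodal_for_mae_dominated_cohort(self, small_cohort):
        joined = small_cohort.counts.merge(
            small_cohort.truth,
            left_on=["Sample_ID", "Chr", "Position"],
            right_on=["sample_id", "chrom", "pos"],
        )
        mae = joined["expression_state"] == "CompleteMAE"
        baf = joined["Count_B"] / (joined["Count_A"] + joined["Count_B"])
        counts, _ = baf_histogram(baf[mae], n_bins=10)
        assert counts[0] + counts[-1] > 0.9 * counts.sum()
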