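"""Stepwise mutation counting, differentiation rates, exact binomial CIs."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_multi_copy, make_table, single_copy_table
from ypedigree.pairwise import (
    clopper_pearson,
    count_multi_copy,
    count_single_copy,
    differentiation_rates,
    median_pairwise_differences,
    pairwise_differences,
    write_prediction_input,
)


class TestCountSingleCopy:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (15, 17, 2),  # two single steps, not one two-step
            (14, 14, 0),
            (23.2, 25.2, 2),  # microvariant offset cancels
            (10, 12, 2),
            (15, 15.2, 1),  # non-stepwise event counts once
        ],
    )
    def test_counts(self, a, b, expected):
        assert count_single_copy(a, b) == expected

    def test_fractional_difference_warns(self, caplog):
        with caplog.at_level(logging.WARNING):
            count_single_copy(15, 15.2)
        assert "non-stepwise" in caplog.text

    @given(
        st.integers(10, 30), st.integers(10, 30), st.integers(10, 30)
    )
    @settings(max_examples=100, derandomize=True)
    def test_triangle_inequality(self, a, b, c):
        """Stepwise counts form a metric on single-copy alleles."""
        assert count_single_copy(a, c) <= count_single_copy(a, b) + count_single_copy(b, c)


class TestCountMultiCopy:
    @pytest.mark.parametrize(
        "a, b, c, expected",
        [
            ((22, 23, 25), (22, 23, 25), 3, 0),
            ((22, 23, 25), (22, 24, 25), 3, 1),
            ((22, 25), (22, 23, 25), 3, 1),  # padding duplicates an own allele
            ((15,), (17,), 1, 2),  # degenerates to the single-copy count
        ],
    )
    def test_examples(self, a, b, c, expected):
        a = tuple(float(x) for x in a)
        b = tuple(float(x) for x in b)
        assert count_multi_copy(a, b, c) == expected

    def test_symmetry_random(self, rng):
        for _ in range(50):
            c = int(rng.integers(1, 5))
            a = tuple(sorted(float(x) for x in rng.integers(18, 28, size=rng.integers(1, c + 1))))
            b = tuple(sorted(float(x) for x in rng.integers(18, 28, size=rng.integers(1, c + 1))))
            assert count_multi_copy(a, b, c) == count_multi_copy(b, a, c)

    def test_matches_brute_force_small_batch(self, rng):
        """Spot check against exhaustive enumeration (full scale run lives in
        the acceptance suite)."""
        for _ in range(30):
            c = int(rng.integers(2, 5))
            a = tuple(sorted(float(x) for x in rng.integers(18, 28, size=rng.integers(1, c + 1))))
            b = tuple(sorted(float(x) for x in rng.integers(18, 28, size=rng.integers(1, c + 1))))
            assert count_multi_copy(a, b, c) == brute_force_multi_copy(a, b, c)


class TestPairwiseDifferences:
    def test_identical_samples_all_zero(self):
        table = single_copy_table(
            "p", {s: {"M1": 14, "M2": 20} for s in ["A", "B", "C"]}
        )
        diffs = pairwise_differences(table)
        assert len(diffs) == 3
        assert (diffs["total"] == 0).all()

    def test_single_marker_two_step_pair(self):
        table = single_copy_table("p", {"A": {"M1": 15, "M2": 9}, "B": {"M1": 17, "M2": 9}})
        diffs = pairwise_differences(table)
        assert diffs.loc[0, "total"] == 2
        assert diffs.loc[0, "M1"] == 2 and diffs.loc[0, "M2"] == 0

    def test_multi_copy_harmonized_within_pedigree(self):
        table = make_table(
            [
                ("p", "A", "DYF399S1", (22.0, 25.0)),
                ("p", "B", "DYF399S1", (22.0, 23.0, 25.0)),
            ]
        )
        diffs = pairwise_differences(table)
        # A pads to three copies by duplicating an own allele: one mutation
        assert diffs.loc[0, "DYF399S1"] == 1

    def test_symmetric_and_nonnegative_random_table(self, rng):
        genotypes = {
            f"S{i}": {f"M{j}": int(rng.integers(12, 18)) for j in range(4)}
            for i in range(10)
        }
        table = single_copy_table("p", genotypes)
        diffs = pairwise_differences(table)
        assert len(diffs) == 45
        markers = ["M0", "M1", "M2", "M3"]
        assert (diffs[markers] >= 0).all().all()
        assert (diffs[markers].sum(axis=1) == diffs["total"]).all()
        # symmetry: recompute with sample order reversed
        rev = single_copy_table("p", dict(reversed(list(genotypes.items()))))
        diffs_rev = pairwise_differences(rev)
        key = ["sample_a", "sample_b"]
        merged = diffs.merge(diffs_rev, on=key, suffixes=("", "_r"))
        assert len(merged) == 45
        assert (merged["total"] == merged["total_r"]).all()

    def test_within_all_pools_across_pedigrees(self):
        table = single_copy_table("p1", {"A": {"M1": 15}})
        extra = single_copy_table("p2", {"B": {"M1": 16}})
        table.data = pd.concat([table.data, extra.data], ignore_index=True)
        diffs = pairwise_differences(table, within="all")
        assert len(diffs) == 1
        assert diffs.loc[0, "total"] == 1


class TestClopperPearson:
    def test_zero_successes_closed_form(self):
        # k=0: upper bound solves (1-p)^n = alpha/2
        low, high = clopper_pearson(0, 10)
        assert low == 0.0
        assert high == pytest.approx(1 - (0.05 / 2) ** (1 / 10), abs=1e-9)

    def test_all_successes_upper_is_one(self):
        low, high = clopper_pearson(10, 10)
        assert high == 1.0
        assert low == pytest.approx((0.05 / 2) ** (1 / 10), abs=1e-9)

    def test_symmetry_about_half(self):
        low, high = clopper_pearson(5, 10)
        assert low == pytest.approx(1 - high, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            clopper_pearson(0, 0)
        with pytest.raises(ValueError):
            clopper_pearson(5, 3)

    def test_coverage_over_simulated_binomials(self, rng):
        """95% CI contains the true p in >=93% of 2000 simulated draws."""
        hits = 0
        n_draws = 2000
        for _ in range(n_draws):
            p = rng.uniform(0.05, 0.95)
            n = int(rng.integers(10, 200))
            k = rng.binomial(n, p)
            low, high = clopper_pearson(int(k), n)
            hits += low <= p <= high
        assert hits / n_draws >= 0.93


class TestDifferentiationRates:
    @staticmethod
    def _distances(pairs):
        return pd.DataFrame(
            pairs, columns=["pedigree_id", "sample_a", "sample_b", "meioses", "lineal"]
        )

    def test_all_pairs_differentiated(self):
        diffs = pd.DataFrame(
            {
                "pedigree_id": ["p"] * 3,
                "sample_a": ["A", "A", "B"],
                "sample_b": ["B", "C", "C"],
                "total": [1, 2, 3],
            }
        )
        dist = self._distances(
            [("p", "A", "B", 1, True), ("p", "A", "C", 2, True), ("p", "B", "C", 2, False)]
        )
        rates = differentiation_rates(diffs, dist)
        assert (rates["rate"] == 1.0).all()
        assert rates.loc[rates["meioses"] == "all", "n_pairs"].iloc[0] == 3

    def test_three_of_ten_distance_two_pairs(self):
        rows, dist_rows = [], []
        for i in range(10):
            rows.append({"pedigree_id": "p", "sample_a": f"A{i}", "sample_b": f"B{i}",
                         "total": 1 if i < 3 else 0})
            dist_rows.append(("p", f"A{i}", f"B{i}", 2, False))
        rates = differentiation_rates(pd.DataFrame(rows), self._distances(dist_rows))
        row = rates[rates["meioses"] == 2].iloc[0]
        assert row["rate"] == pytest.approx(0.30)
        low, high = clopper_pearson(3, 10)
        assert row["ci_low"] == pytest.approx(low)
        assert row["ci_high"] == pytest.approx(high)
        assert row["ci_low"] <= row["rate"] <= row["ci_high"]

    def test_no_shared_pairs_warns_and_returns_empty(self, caplog):
        diffs = pd.DataFrame(
            {"pedigree_id": ["p"], "sample_a": ["A"], "sample_b": ["B"], "total": [1]}
        )
        dist = self._distances([("q", "X", "Y", 1, True)])
        with caplog.at_level(logging.WARNING):
            rates = differentiation_rates(diffs, dist)
        assert rates.empty
        assert "no meiotic distance" in caplog.text


class TestMedianPairwiseDifferences:
    def test_small_and_degenerate(self):
        assert median_pairwise_differences(pd.DataFrame({"total": [0, 1, 2]})) == 1
        assert median_pairwise_differences(pd.DataFrame({"total": [0, 0]})) == 0
        with pytest.raises(ValueError):
            median_pairwise_differences(pd.DataFrame({"total": []}))

    def test_matches_sort_and_pick_oracle(self, rng):
        totals = rng.integers(0, 20, size=101)
        naive = sorted(totals)[50]
        assert median_pairwise_differences(pd.DataFrame({"total": totals})) == naive


class TestWritePredictionInput:
    def test_column_order_follows_marker_set(self, tmp_path):
        diffs = pd.DataFrame(
            {
                "pedigree_id": ["p"], "sample_a": ["A"], "sample_b": ["B"],
                "M2": [1], "M1": [0], "M3": [2], "total": [3],
            }
        )
        out = write_prediction_input(diffs, ["M1", "M2", "M3"], tmp_path / "f.csv")
        assert list(out.columns) == ["pedigree_id", "sample_a", "sample_b", "M1", "M2", "M3"]
        assert out.iloc[0][["M1", "M2", "M3"]].tolist() == [0, 1, 2]
        reread = pd.read_csv(tmp_path / "f.csv")
        assert list(reread.columns) == list(out.columns)

    def test_missing_marker_column_errors(self):
        diffs = pd.DataFrame(
            {"pedigree_id": ["p"], "sample_a": ["A"], "sample_b": ["B"], "M1": [0]}
        )
        with pytest.raises(ValueError, match="M9"):
            write_prediction_input(diffs, ["M1", "M9"])

    def test_schema_compatible_with_simulator_output(self):
        from ypedigree.simulate import MutationModelConfig, simulate_pairs

        config = MutationModelConfig.from_rates(
            {"M1": 0.01, "DYF399S1": 0.06}, copies={"DYF399S1": 3}
        )
        train = simulate_pairs(config, [1, 2], 5, seed=0)
        diffs = pd.DataFrame(
            {"pedigree_id": ["p"], "sample_a": ["A"], "sample_b": ["B"],
             "M1": [0], "DYF399S1": [1], "total": [1]}
        )
        features = write_prediction_input(diffs, config.markers)
        assert list(features.columns[3:]) == [
            c for c in train.columns if c != "generation"
        ]
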