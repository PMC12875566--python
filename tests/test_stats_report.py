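import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mostrip.risk_stratification import assign_tertiles
from mostrip.stats_report import (
    condition_regression,
    paired_wilcoxon,
    summarize_steps,
)


def enumeration_oracle(diffs):
    """Two-sided exact signed-rank p by brute force over all sign patterns."""
    from scipy.stats import rankdata

    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mu = ranks.sum() / 2.0
    count = 0
    total = 0
    for signs in itertools.product([0, 1], repeat=len(d)):
        w = sum(r for r, s in zip(ranks, signs) if s)
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            count += 1
    return count / total


class TestPairedWilcoxon:
    def test_five_concordant_pairs(self):
        pairs = [(i + 1.0, float(i)) for i in range(5)]
        res = paired_wilcoxon(pairs)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / 32)

    def test_sign_symmetry(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10)
        c = 0.7
        a = paired_wilcoxon(np.column_stack([x, x + c]))
        b = paired_wilcoxon(np.column_stack([x + c, x]))
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    def test_zero_differences_dropped(self):
        pairs = [(1.0, 1.0), (2.0, 1.0), (3.0, 1.0), (4.0, 1.0)]
        res = paired_wilcoxon(pairs)
        assert res.n_pairs == 3

    def test_all_zero_differences_raise(self):
        with pytest.raises(ValueError, match="zero"):
            paired_wilcoxon([(1.0, 1.0), (2.0, 2.0)])

    def test_exact_vs_normal_at_n100(self):
        rng = np.random.default_rng(42)
        pairs = np.column_stack([rng.normal(size=100), rng.normal(size=100)])
        # exact DP is still tractable at n=100 when forced
        exact = paired_wilcoxon(pairs, force_method="exact")
        approx = paired_wilcoxon(pairs, force_method="normal")
        assert exact.method == "exact" and approx.method == "normal-approx"
        assert abs(exact.p_value - approx.p_value) < 0.01

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_exact_p_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 11))
        # half-integer values create ties in |d| with positive probability
        diffs = rng.integers(-4, 5, n) + 0.5 * rng.integers(0, 2, n)
        if np.all(diffs == 0):
            diffs[0] = 1.0
        pairs = np.column_stack([diffs, np.zeros(n)])
        res = paired_wilcoxon(pairs)
        assert res.p_value == pytest.approx(enumeration_oracle(diffs), abs=1e-12)


class TestSummarizeSteps:
    def test_odd_n_quartiles(self):
        table = pd.DataFrame(
            {"label": ["a"] * 5, "mos": [1.0, 2, 3, 4, 5], "valid": True}
        )
        (row,) = summarize_steps(table).itertuples()
        assert (row.median, row.iqr_low, row.iqr_high) == (3.0, 2.0, 4.0)
        assert row.ci_low <= row.mean <= row.ci_high

    def test_single_value_degenerate_ci(self):
        table = pd.DataFrame({"label": ["a"], "mos": [7.5], "valid": True})
        (row,) = summarize_steps(table).itertuples()
        assert row.median == row.mean == 7.5
        assert row.ci_low == row.ci_high == 7.5

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(
            {
                "label": rng.choice(["a", "b"], 50),
                "mos": rng.normal(size=50),
                "valid": True,
            }
        )
        a = summarize_steps(table).sort_values("label").reset_index(drop=True)
        b = (
            summarize_steps(table.sample(frac=1.0, random_state=0))
            .sort_values("label")
            .reset_index(drop=True)
        )
        pd.testing.assert_frame_equal(a, b)

    def test_injected_offset_changes_sign_of_perturbed_median(self):
        rng = np.random.default_rng(2)
        rows = []
        for lab, mean in (("baseline", 119.0), ("perturbed", -200.0)):
            rows += [
                {"label": lab, "mos": rng.normal(mean, 30.0), "valid": True}
                for _ in range(200)
            ]
        res = summarize_steps(pd.DataFrame(rows)).set_index("label")
        assert res.loc["perturbed", "median"] < 0 < res.loc["baseline", "median"]

    def test_empty_group_warns(self):
        table = pd.DataFrame(
            {"label": ["a", "b"], "mos": [1.0, np.nan], "valid": [True, True]}
        )
        with pytest.warns(UserWarning, match="omitted"):
            res = summarize_steps(table)
        assert list(res["label"]) == ["a"]


class TestConditionRegression:
    def _mos(self, means, n=30, sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i, (pid, tert_mean) in enumerate(means.items()):
            rows += [
                {
                    "participant_id": pid,
                    "condition": "c",
                    "label": "perturbed",
                    "mos": tert_mean + sd * rng.standard_normal(),
                    "valid": True,
                }
                for _ in range(n)
            ]
        return pd.DataFrame(rows)

    def test_two_group_coefficient_equals_mean_difference(self):
        # 9 participants -> tertiles 3/3/3; low mean 91 mm, high mean 163 mm
        profiles = assign_tertiles({f"P{i}": float(i) for i in range(9)})
        means = {f"P{i}": (91.0 if i < 3 else (120.0 if i < 6 else 163.0)) for i in range(9)}
        table = self._mos(means)
        res = condition_regression(table, profiles)
        high = res.query("term == 'tertile_high'")["coef"].iloc[0]
        assert high == pytest.approx(163.0 - 91.0, abs=1e-9)

    def test_identical_groups_zero_coefficient(self):
        profiles = assign_tertiles({f"P{i}": float(i) for i in range(9)})
        table = self._mos({f"P{i}": 100.0 for i in range(9)})
        res = condition_regression(table, profiles)
        for term in ("tertile_mid", "tertile_high"):
            assert res.query("term == @term")["coef"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_location_equivariance(self):
        profiles = assign_tertiles({f"P{i}": float(i) for i in range(9)})
        means = {f"P{i}": float(10 * i) for i in range(9)}
        table = self._mos(means, sd=5.0, seed=3)
        a = condition_regression(table, profiles)
        shifted = table.assign(mos=table["mos"] + 50.0)
        b = condition_regression(shifted, profiles)
        merged = a.merge(b, on=["condition", "step_label", "term"], suffixes=("_a", "_b"))
        const = merged["term"] == "const"
        np.testing.assert_allclose(
            merged.loc[const, "coef_b"], merged.loc[const, "coef_a"] + 50.0, atol=1e-9
        )
        np.testing.assert_allclose(
            merged.loc[~const, "coef_b"], merged.loc[~const, "coef_a"], atol=1e-9
        )

    def test_missing_group_raises(self):
        profiles = assign_tertiles({f"P{i}": float(i) for i in range(9)})
        table = self._mos({"P0": 100.0, "P1": 110.0})  # low tertile only
        with pytest.raises(ValueError, match="rank-deficient"):
            condition_regression(table, profiles)

    def test_continuous_covariate_mode(self):
        profiles = assign_tertiles({f"P{i}": float(i) for i in range(9)})
        means = {f"P{i}": 100.0 + 2.0 * i for i in range(9)}
        res = condition_regression(self._mos(means), profiles, covariate="risk_score")
        slope = res.query("term == 'risk_score'")["coef"].iloc[0]
        assert slope == pytest.approx(2.0, abs=1e-9)
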