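"""Replicate odds ratios, PRS-factor estimation, ANOVA stability, FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from prsfactor.factor import (
    NON_REFERENCE_GROUPS,
    anova_oneway,
    anova_stability,
    estimate_prs_factor,
    fdr_adjust,
    or_point,
    or_replicates,
)


class TestORPoint:
    def test_symmetric_table_gives_unity(self):
        assert or_point(10, 100, 10, 100).value == pytest.approx(1.0)

    def test_hand_example(self):
        assert or_point(20, 90, 10, 100).value == pytest.approx(
            (20 / 10) / (90 / 100)
        )

    def test_zero_cell_haldane_correction(self):
        pt = or_point(0, 100, 10, 100)
        assert pt.corrected
        expected = (0.5 / 10.5) / (100.5 / 100.5)
        assert pt.value == pytest.approx(expected)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            or_point(1, 1, 0, 0)

    def test_cross_product_identity(self, rng):
        """Ratio-of-proportions OR equals the 2x2 cross-product ratio."""
        for _ in range(1000):
            d, h, dr, hr = rng.integers(1, 500, size=4)
            assert or_point(d, h, dr, hr).value == pytest.approx(
                (d * hr) / (h * dr), rel=1e-12
            )


def _toy_groups(n_per_group=50, p_case=0.2, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(1, 11):
        for _ in range(n_per_group):
            rows.append({"prs_group": g, "case": rng.random() < p_case})
    return pd.DataFrame(rows)


class TestORReplicates:
    def test_counting(self):
        groups = _toy_groups()
        rng = np.random.default_rng(1)
        rep = or_replicates(groups, "entire", None, 10, rng)
        assert len(rep) == 8 * 10
        assert set(rep["prs_group"]) == set(NON_REFERENCE_GROUPS)

    def test_deterministic_under_seed(self):
        groups = _toy_groups()
        a = or_replicates(groups, "s", None, 5, np.random.default_rng(3))
        b = or_replicates(groups, "s", None, 5, np.random.default_rng(3))
        pd.testing.assert_frame_equal(a, b)

    def test_replicates_partition_members(self):
        groups = _toy_groups(n_per_group=53)
        rep = or_replicates(groups, "entire", None, 10,
                            np.random.default_rng(2))
        for g in NON_REFERENCE_GROUPS:
            sub = rep[rep["prs_group"] == g]
            assert (sub["d"] + sub["h"]).sum() == 53
            sizes = sub["d"] + sub["h"]
            assert sizes.max() - sizes.min() <= 1

    def test_too_small_group_suggests_smaller_k(self):
        groups = _toy_groups(n_per_group=4)
        with pytest.raises(ValueError, match="smaller k"):
            or_replicates(groups, "entire", None, 5, np.random.default_rng(0))

    def test_replicate_mean_estimates_full_sample_or(self, sim20k):
        """Replicate means agree with the single full-sample OR per tenth."""
        groups = pd.DataFrame({"prs_group": sim20k["prs_group"],
                               "case": sim20k["prevalent_cvd"].astype(bool)})
        rep = or_replicates(groups, "entire", None, 10,
                            np.random.default_rng(5))
        ref = groups[groups["prs_group"].isin((5, 6))]
        d_ref = int(ref["case"].sum())
        h_ref = int((~ref["case"]).sum())
        for g in NON_REFERENCE_GROUPS:
            sub = groups[groups["prs_group"] == g]
            full = or_point(int(sub["case"].sum()), int((~sub["case"]).sum()),
                            d_ref, h_ref).value
            ors = rep.loc[rep["prs_group"] == g, "odds_ratio"]
            se = ors.std(ddof=1) / np.sqrt(len(ors))
            assert abs(ors.mean() - full) < 3 * se


class TestEstimate:
    def test_degenerate_replicates_zero_width(self):
        rep = pd.DataFrame(
            {"prs_group": np.repeat(NON_REFERENCE_GROUPS, 3),
             "odds_ratio": 1.0}
        )
        tab = estimate_prs_factor(rep)
        assert (tab.loc[tab.index != "5/6", "mean_or"] == 1.0).all()
        assert (tab.loc["1", "ci_high"] - tab.loc["1", "ci_low"]) == 0.0

    def test_textbook_t_interval(self):
        rep = pd.DataFrame(
            {"prs_group": np.repeat(NON_REFERENCE_GROUPS, 3),
             "odds_ratio": np.tile([1.5, 1.7, 1.9], 8)}
        )
        tab = estimate_prs_factor(rep)
        half = stats.t.ppf(0.975, 2) * np.std([1.5, 1.7, 1.9], ddof=1) / np.sqrt(3)
        assert tab.loc["10", "mean_or"] == pytest.approx(1.7)
        assert tab.loc["10", "ci_low"] == pytest.approx(1.7 - half)
        assert tab.loc["10", "ci_high"] == pytest.approx(1.7 + half)

    def test_reference_row_fixed_at_unity(self):
        rep = pd.DataFrame(
            {"prs_group": np.repeat(NON_REFERENCE_GROUPS, 2),
             "odds_ratio": 2.0}
        )
        tab = estimate_prs_factor(rep)
        assert tab.loc["5/6", "mean_or"] == 1.0

    def test_missing_tenth_rejected(self):
        rep = pd.DataFrame({"prs_group": [1, 2], "odds_ratio": [1.0, 1.0]})
        with pytest.raises(ValueError, match="missing"):
            estimate_prs_factor(rep)

    def test_monotone_factor_on_multiplicative_simulation(self, factor_results):
        ors = factor_results.factor_table["mean_or"]
        assert ors.is_monotonic_increasing


class TestANOVA:
    def test_identical_groups_give_f_zero(self):
        res = anova_oneway([np.ones(5), np.ones(4), np.ones(6)])
        assert res["f_value"] == 0.0
        assert res["p_value"] == 1.0

    def test_degrees_of_freedom_with_four_groups(self, rng):
        res = anova_oneway([rng.normal(size=5) for _ in range(4)])
        assert res["df_between"] == 3

    def test_matches_scipy_f_oneway(self, rng):
        for _ in range(20):
            groups = [rng.normal(size=rng.integers(3, 9)) for _ in range(4)]
            res = anova_oneway(groups)
            f, p = stats.f_oneway(*groups)
            assert res["f_value"] == pytest.approx(f, abs=1e-10)
            assert res["p_value"] == pytest.approx(p, abs=1e-10)

    def test_hand_sums_of_squares_oracle(self, rng):
        """Explicit deviation-from-mean arithmetic on a small fixture."""
        groups = [rng.normal(loc=m, size=4) for m in (0.0, 0.5, 1.0)]
        res = anova_oneway(groups)
        all_vals = np.concatenate(groups)
        grand = all_vals.mean()
        ss_b = sum(4 * (g.mean() - grand) ** 2 for g in groups)
        ss_w = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f = (ss_b / 2) / (ss_w / 9)
        assert res["sum_sq"] == pytest.approx(ss_b, abs=1e-10)
        assert res["f_value"] == pytest.approx(f, abs=1e-10)

    def test_stability_table_structure(self, factor_results):
        tab = factor_results.stability["clinical_categories"]
        assert list(tab.index) == list(NON_REFERENCE_GROUPS)
        # entire cohort + three clinical categories -> 3 df between groups
        assert (tab["df_between"] == 3).all()
        assert (tab["fdr_q"] >= tab["p_value"] - 1e-12).all()

    def test_log_scale_matches_anova_on_logged_ors(self, rng):
        entire = pd.DataFrame(
            {"prs_group": np.repeat(NON_REFERENCE_GROUPS, 5),
             "odds_ratio": rng.uniform(0.5, 2.0, 40)}
        )
        other = entire.assign(odds_ratio=rng.uniform(0.5, 2.0, 40))
        res_log = anova_stability(entire, {"s": other}, scale="log")
        logged_e = entire.assign(odds_ratio=np.log(entire["odds_ratio"]))
        logged_o = other.assign(odds_ratio=np.log(other["odds_ratio"]))
        res_manual = anova_stability(logged_e, {"s": logged_o}, scale="or")
        assert np.allclose(res_log["f_value"], res_manual["f_value"])
        with pytest.raises(ValueError, match="scale"):
            anova_stability(entire, {"s": other}, scale="bad")

    def test_anova_stability_flags_a_shifted_stratum(self, rng):
        entire = pd.DataFrame(
            {"prs_group": np.repeat(NON_REFERENCE_GROUPS, 10),
             "odds_ratio": rng.normal(1.0, 0.05, 80)}
        )
        shifted = entire.copy()
        shifted["odds_ratio"] = rng.normal(2.0, 0.05, 80)
        res = anova_stability(entire, {"strange": shifted})
        assert (res["fdr_q"] < 0.05).all()


class TestFDR:
    def test_hand_benjamini_hochberg(self):
        q = fdr_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, 0.04)

    def test_matches_step_up_definition(self, rng):
        p = rng.uniform(size=8)
        q = fdr_adjust(p)
        m = len(p)
        order = np.argsort(p)
        ranked = p[order] * m / (np.arange(m) + 1)
        expected = np.minimum.accumulate(ranked[::-1])[::-1]
        expected = np.minimum(expected, 1.0)
        assert np.allclose(q[order], expected)

    def test_monotone_in_p(self):
        p = np.array([0.001, 0.5, 0.04, 0.2])
        q = fdr_adjust(p)
        assert np.all(np.diff(q[np.argsort(p)]) >= -1e-12)
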