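"""Total-risk model, reclassification, Cox/C-index, NRI, bootstrap."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from prsfactor import (
    ReclassificationTable,
    categorical_nri,
    compute_total_risk,
    concordance_index,
    export_sankey,
    fit_cox,
)
from prsfactor.datasets import ukb_reclassification_counts
from prsfactor.integration import bootstrap_metric


def _factor_table(values=None):
    labels = ["1", "2", "3", "4", "5/6", "7", "8", "9", "10"]
    if values is None:
        values = [1.0] * 9
    return pd.DataFrame({"mean_or": values},
                        index=pd.Index(labels, name="prs_group"))


class TestTotalRisk:
    def test_direct_product(self):
        tab = _factor_table([0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.4, 1.72])
        out = compute_total_risk(pd.Series([0.05]), [10], tab, [45])
        assert out["total_risk"].iloc[0] == pytest.approx(0.05 * 1.72)
        assert out["original_category"].iloc[0] == "intermediate"
        assert out["new_category"].iloc[0] == "high"  # 8.6% >= 7.5% under 50

    def test_unit_factor_identity(self):
        out = compute_total_risk(pd.Series([0.04, 0.2]), [3, 8],
                                 _factor_table(), [55, 60])
        assert np.allclose(out["total_risk"], [0.04, 0.2])
        assert (out["original_category"] == out["new_category"]).all()

    def test_cap_rule(self):
        tab = _factor_table([1.0] * 8 + [1.72])
        out = compute_total_risk(pd.Series([0.8]), [10], tab, [55])
        assert out["total_risk"].iloc[0] == 1.0

    def test_upgrade_only_floors_factor_at_one(self):
        tab = _factor_table([0.5] * 4 + [1.0] + [2.0] * 4)
        out = compute_total_risk(pd.Series([0.06, 0.06]), [1, 10], tab,
                                 [55, 55], upgrade_only=True)
        assert out["prs_factor"].tolist() == [1.0, 2.0]

    def test_missing_tenth_rejected(self):
        tab = _factor_table().drop(index="10")
        with pytest.raises(ValueError, match="10"):
            compute_total_risk(pd.Series([0.05]), [10], tab, [55])


class TestReclassification:
    def test_unit_factor_gives_diagonal_table(self, rng):
        n = 500
        cats = rng.choice(["low", "intermediate", "high"], n)
        rec = ReclassificationTable.from_cohort(cats, cats,
                                               rng.integers(0, 2, n))
        off = rec.table[(rec.table["origin"] != rec.table["destination"])]
        assert (off["n"] == 0).all()
        assert len(export_sankey(rec)) == 3

    def test_count_conservation(self, rng):
        n = 1000
        old = rng.choice(["low", "intermediate", "high"], n)
        new = rng.choice(["low", "intermediate", "high"], n)
        rec = ReclassificationTable.from_cohort(old, new, rng.integers(0, 2, n))
        assert rec.table["n"].sum() == n
        for cat in ("low", "intermediate", "high"):
            assert rec.origin_total(cat) == (old == cat).sum()
        assert export_sankey(rec)["count"].sum() == n

    def test_published_counts_reproduce_headline_shares(self):
        rec = ukb_reclassification_counts()
        assert rec.moved_share_pct("intermediate", "high") == pytest.approx(
            100 * 13886 / 145337
        )
        assert rec.relative_inflow_pct("intermediate", "high") == pytest.approx(
            100 * 13886 / 24549
        )
        assert rec.incidence_ratio("intermediate", "high") == pytest.approx(
            8.08 / 4.08
        )
        assert rec.moved_share_pct("high", "intermediate") == pytest.approx(
            100 * 8291 / 24549
        )
        assert rec.max_jump() == 1  # no one crosses two categories

    def test_published_counts_sankey_links(self):
        links = export_sankey(ukb_reclassification_counts())
        assert len(links) == 7  # 3 diagonal + 4 occupied off-diagonal cells
        assert links["count"].sum() == 297_201

    def test_round_trip_preserves_counts(self, tmp_path):
        from prsfactor.io import (
            read_reclassification_table,
            write_reclassification_table,
        )

        rec = ukb_reclassification_counts()
        path = tmp_path / "reclass.tsv"
        write_reclassification_table(rec, path)
        back = read_reclassification_table(path)
        assert back.table["n"].tolist() == rec.table["n"].tolist()

    def test_risk_factor_prevalences(self):
        old = ["low"] * 4
        new = ["low", "low", "intermediate", "intermediate"]
        rf = pd.DataFrame({"smoking": [1, 0, 1, 1]})
        rec = ReclassificationTable.from_cohort(old, new, [0, 0, 1, 0],
                                               risk_factors=rf)
        cell = rec.table[(rec.table["origin"] == "low")
                         & (rec.table["destination"] == "intermediate")]
        assert cell["smoking_pct"].iloc[0] == pytest.approx(100.0)
        assert cell["incidence_pct"].iloc[0] == pytest.approx(50.0)


def _efron_neg_loglik(beta, time, event, x):
    """Hand-written Efron partial log-likelihood for one covariate."""
    ll = 0.0
    for t in np.unique(time[event == 1]):
        dead = (time == t) & (event == 1)
        at_risk = time >= t
        d = dead.sum()
        theta = np.exp(beta * x)
        sum_risk = theta[at_risk].sum()
        sum_dead = theta[dead].sum()
        ll += beta * x[dead].sum()
        for l in range(d):
            ll -= np.log(sum_risk - (l / d) * sum_dead)
    return -ll


class TestSurvivalMetrics:
    def test_perfect_and_reversed_ordering(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        event = np.ones(5, dtype=int)
        score = np.array([5.0, 4.0, 3.0, 2.0, 1.0])  # higher -> earlier event
        assert concordance_index(time, event, score) == 1.0
        assert concordance_index(time, event, -score) == 0.0

    def test_concordance_matches_all_pairs_oracle(self, rng):
        """8 subjects with censoring and one tied time vs explicit pair rules."""
        time = np.array([2.0, 3.0, 3.0, 5.0, 6.0, 7.0, 8.0, 9.0])
        event = np.array([1, 1, 0, 1, 0, 1, 0, 1])
        score = rng.normal(size=8)

        num = den = 0.0
        n = len(time)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                if time[i] == time[j]:
                    usable = event[i] == 1 and event[j] == 0
                elif time[i] < time[j]:
                    usable = event[i] == 1
                else:
                    usable = False
                if not usable:
                    continue
                den += 1
                if score[i] > score[j]:
                    num += 1
                elif score[i] == score[j]:
                    num += 0.5
        expected = num / den
        assert concordance_index(time, event, score) == pytest.approx(
            expected, abs=1e-6
        )

    def test_cox_beta_matches_partial_likelihood_oracle(self):
        time = np.array([2.0, 3.0, 3.0, 5.0, 6.0, 7.0, 8.0, 9.0])
        event = np.array([1, 1, 1, 1, 0, 1, 0, 1])
        x = np.array([1.2, 0.8, 1.5, 0.3, 0.9, -0.2, 0.4, -1.0])
        beta, se = fit_cox(time, event, x)
        res = minimize_scalar(
            _efron_neg_loglik, bounds=(-5, 5), args=(time, event, x),
            method="bounded", options={"xatol": 1e-10},
        )
        assert beta == pytest.approx(res.x, abs=1e-6)
        assert se > 0

    def test_cox_requires_events(self):
        with pytest.raises(ValueError, match="events"):
            fit_cox([1.0, 2.0], [0, 0], [0.1, 0.2])


class TestNRI:
    def test_no_movement_is_zero(self):
        cats = ["low", "high", "intermediate"]
        res = categorical_nri(cats, cats, [1, 0, 0])
        assert res["nri"] == 0.0

    def test_maximal_reclassification(self):
        old = ["low", "low", "high", "high"]
        new = ["high", "high", "low", "low"]
        event = [1, 1, 0, 0]
        assert categorical_nri(old, new, event)["nri"] == pytest.approx(2.0)

    def test_toy_hand_arithmetic(self):
        old = ["intermediate"] * 100
        new = (
            ["high"] * 4 + ["low"] * 1 + ["intermediate"] * 5      # events
            + ["high"] * 9 + ["low"] * 18 + ["intermediate"] * 63  # non-events
        )
        event = [1] * 10 + [0] * 90
        res = categorical_nri(old, new, event)
        assert res["event_component"] == pytest.approx(0.4 - 0.1)
        assert res["nonevent_component"] == pytest.approx(0.2 - 0.1)
        assert res["nri"] == pytest.approx(0.4)

    def test_requires_both_outcomes(self):
        with pytest.raises(ValueError, match="events"):
            categorical_nri(["low"], ["low"], [1])


class TestBootstrap:
    def test_constant_metric_zero_width(self):
        df = pd.DataFrame({"x": np.ones(50)})
        res = bootstrap_metric(lambda d: float(d["x"].mean()), df, b=50, seed=1)
        assert res["ci_low"] == res["ci_high"] == res["mean"] == 1.0

    def test_deterministic_under_seed(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=100)})
        f = lambda d: float(d["x"].mean())  # noqa: E731
        a = bootstrap_metric(f, df, b=100, seed=5)
        b = bootstrap_metric(f, df, b=100, seed=5)
        assert a == b

    def test_percentile_interval_coverage(self):
        """~95% of bootstrap intervals for a normal mean cover the truth."""
        covered = 0
        reps = 200
        for k in range(reps):
            r = np.random.default_rng(1000 + k)
            df = pd.DataFrame({"x": r.normal(0.0, 1.0, 60)})
            res = bootstrap_metric(lambda d: float(d["x"].mean()), df,
                                   b=150, seed=k)
            covered += res["ci_low"] <= 0.0 <= res["ci_high"]
        assert covered / reps > 0.88

    def test_failing_metric_raises_after_retries(self):
        df = pd.DataFrame({"x": np.ones(10)})

        def bad(_):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="resamples"):
            bootstrap_metric(bad, df, b=2, seed=0, max_retries=2)
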