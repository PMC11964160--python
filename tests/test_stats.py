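import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from sensillum.stats import (
    fit_parameter_slope,
    run_group_comparison,
    run_rm_comparison,
    slopes_from_features,
)

# ---------------------------------------------------------------------------
# independent oracles (brute-force textbook formulas)


def oracle_f(groups):
    """Between/within mean-square ratio, straight from the definitions."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_b = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_w = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = allv.size - len(groups)
    return (ss_b / df_b) / (ss_w / df_w)


def oracle_h(groups):
    """Kruskal-Wallis H with tie correction, from rank sums."""
    allv = np.concatenate(groups)
    n = allv.size
    ranks = sps.rankdata(allv)
    bounds = np.cumsum([0] + [g.size for g in groups])
    h = 12.0 / (n * (n + 1)) * sum(
        ranks[bounds[i] : bounds[i + 1]].sum() ** 2 / groups[i].size
        for i in range(len(groups))
    ) - 3 * (n + 1)
    _, counts = np.unique(allv, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / correction


def oracle_rm_f(data):
    """RM-ANOVA F from the raw sum-of-squares decomposition."""
    n, k = data.shape
    grand = data.mean()
    ss_cond = n * np.sum((data.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((data.mean(axis=1) - grand) ** 2)
    ss_err = np.sum((data - grand) ** 2) - ss_cond - ss_subj
    return (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))


# ---------------------------------------------------------------------------


class TestFitParameterSlope:
    def test_constant_values(self):
        rec = fit_parameter_slope(np.arange(24) * 5.0, np.full(24, 3.3))
        assert rec.slope == 0.0
        assert rec.gated_slope == 0.0

    def test_exact_line_significant(self):
        t = np.arange(24) * 5.0
        rec = fit_parameter_slope(t, 2.0 + 0.05 * t)
        assert rec.slope == pytest.approx(0.05)
        assert rec.gated_slope == pytest.approx(0.05)  # zero residual => significant
        assert rec.p_slope == 0.0

    def test_missing_values_dropped_pairwise(self):
        t = np.arange(10, dtype=float)
        y = 1.0 + 2.0 * t
        y[3] = np.nan
        t2 = t.copy()
        t2[7] = np.nan
        rec = fit_parameter_slope(t2, y)
        assert rec.n_points == 8
        assert rec.slope == pytest.approx(2.0)

    def test_fewer_than_3_points(self):
        rec = fit_parameter_slope(np.array([0.0, 5.0]), np.array([1.0, 2.0]))
        assert math.isnan(rec.slope)
        assert rec.gated_slope == 0.0
        assert rec.n_points == 2

    def test_zero_time_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            fit_parameter_slope(np.zeros(5), np.arange(5.0))

    def test_gating_matches_linregress_oracle(self):
        # oracle: scipy linregress two-sided slope p at alpha = 0.05
        rng = np.random.default_rng(0)
        t = np.arange(24) * 5.0
        agree = 0
        for _ in range(100):
            y = 0.05 * t + rng.normal(0, rng.uniform(0.5, 5.0), t.size)
            rec = fit_parameter_slope(t, y)
            lr = sps.linregress(t, y)
            assert rec.slope == pytest.approx(lr.slope, rel=1e-12)
            assert rec.p_slope == pytest.approx(lr.pvalue, rel=1e-9)
            if lr.pvalue < 0.05:
                assert rec.gated_slope == pytest.approx(lr.slope, rel=1e-12)
                assert rec.gated_slope != 0.0
            else:
                assert rec.gated_slope == 0.0
            agree += 1
        assert agree == 100

    def test_slopes_from_features_labels(self):
        df = pd.DataFrame(
            dict(
                experiment_id=["a"] * 4 + ["b"] * 4,
                condition=["ctrl"] * 4 + ["drug"] * 4,
                zt=["ZT1-3"] * 8,
                stimulation_time=list(range(4)) * 2,
                f6ap=[150, 149, 148, 147, 150, 140, 130, 120],
                latency=[2.0, 2.0, 2.0, 2.0] * 2,
            )
        )
        out = slopes_from_features(df, parameters=("f6ap", "latency"))
        assert len(out) == 4
        a_f6ap = out[(out.experiment_id == "a") & (out.parameter == "f6ap")].iloc[0]
        assert a_f6ap.slope == pytest.approx(-1.0)
        assert set(out["condition"]) == {"ctrl", "drug"}


class TestGroupComparison:
    def test_identical_groups(self):
        res = run_group_comparison({"a": [1.0, 1, 1], "b": [1.0, 1, 1]})
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_f_matches_oracle_on_integers(self):
        groups = {
            "g1": np.array([3.0, 4, 5, 6, 4]),
            "g2": np.array([6.0, 7, 8, 9, 7]),
            "g3": np.array([2.0, 3, 4, 5, 3]),
            "g4": np.array([5.0, 6, 7, 8, 6]),
        }
        res = run_group_comparison(groups)
        assert res.test == "one-way ANOVA"
        assert res.statistic == pytest.approx(oracle_f(list(groups.values())), rel=1e-12)
        assert res.df_between == 3
        assert res.df_residual == 16

    def test_rank_branch_on_nonpositive_heavy_tails(self):
        rng = np.random.default_rng(1)
        heavy = sps.cauchy.rvs(size=20, random_state=rng) - 5.0  # non-normal, negative values
        groups = {"a": heavy, "b": rng.normal(0, 1, 20), "c": rng.normal(0, 1, 20)}
        res = run_group_comparison(groups)
        assert res.test == "ANOVA on ranks"
        assert res.posthoc["method"].eq("Dunn").all()
        assert res.df_residual is None
        assert any("non-positive" in n for n in res.notes)

    def test_log_branch_on_lognormal(self):
        rng = np.random.default_rng(2)
        groups = {
            "a": np.exp(rng.normal(0, 1, 25)),
            "b": np.exp(rng.normal(0.5, 1, 25)),
            "c": np.exp(rng.normal(1.0, 1, 25)),
        }
        res = run_group_comparison(groups)
        assert res.test == "one-way ANOVA"
        assert res.transform == "log"
        assert res.posthoc["method"].eq("Tukey").all()

    def test_variance_failure_goes_to_ranks(self):
        rng = np.random.default_rng(3)
        groups = {
            "a": rng.normal(0, 0.1, 20),
            "b": rng.normal(0, 5.0, 20),
            "c": rng.normal(0, 0.1, 20),
        }
        res = run_group_comparison(groups)
        # normality can pass while Levene fails -> rank branch
        if res.normality_pass:
            assert res.test == "ANOVA on ranks"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            run_group_comparison({"a": [1.0, 2.0], "b": []})

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            run_group_comparison({"a": [1.0, 2.0]})

    def test_branch_exclusivity_and_posthoc_match(self):
        rng = np.random.default_rng(4)
        for i in range(25):
            k = rng.integers(2, 5)
            groups = {
                f"g{j}": rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), rng.integers(4, 10))
                for j in range(k)
            }
            res = run_group_comparison(groups)
            assert res.test in ("one-way ANOVA", "ANOVA on ranks")
            expected = "Tukey" if res.test == "one-way ANOVA" else "Dunn"
            assert res.posthoc["method"].eq(expected).all()
            assert res.df_between == k - 1
            assert len(res.posthoc) == k * (k - 1) // 2

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_f_and_h_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 5))
        groups = [rng.normal(rng.uniform(-2, 2), 1.0, int(rng.integers(3, 8)))
                  for _ in range(k)]
        f, _ = sps.f_oneway(*groups)
        h, _ = sps.kruskal(*groups)
        assert f == pytest.approx(oracle_f(groups), rel=1e-9)
        assert h == pytest.approx(oracle_h(groups), rel=1e-9)
        # full decision-tree result uses one of the two statistics
        res = run_group_comparison({f"g{i}": g for i, g in enumerate(groups)})
        expected = f if res.test == "one-way ANOVA" and res.transform == "none" else None
        if expected is not None:
            assert res.statistic == pytest.approx(expected, rel=1e-9)
        elif res.test == "ANOVA on ranks":
            assert res.statistic == pytest.approx(h, rel=1e-9)


class TestDunn:
    def test_obvious_difference_significant(self):
        rng = np.random.default_rng(5)
        groups = {"lo": rng.normal(0, 1, 15), "hi": rng.normal(10, 1, 15),
                  "lo2": rng.normal(0, 1, 15)}
        res = run_group_comparison(
            {k: np.concatenate([v, [-50.0]]) for k, v in groups.items()}  # break normality
        )
        assert res.test == "ANOVA on ranks"
        ph = res.posthoc.set_index(["group_a", "group_b"])
        assert ph.loc[("lo", "hi"), "p"] < 0.05
        assert ph.loc[("lo", "lo2"), "p"] > 0.05


class TestRmComparison:
    def test_zero_differences(self):
        per_animal = {f"a{i}": {"c1": float(i), "c2": float(i)} for i in range(6)}
        res = run_rm_comparison(per_animal)
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(6)
        data = rng.normal(10, 2, size=(9, 4)) + np.array([0.0, 0.5, 1.0, 0.2])
        per_animal = {
            f"a{i}": {f"c{j}": data[i, j] for j in range(4)} for i in range(9)
        }
        res = run_rm_comparison(per_animal)
        assert res.statistic == pytest.approx(oracle_rm_f(data), rel=1e-12)
        assert res.df_between == 3
        assert res.df_residual == 24

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        data = rng.normal(5, 1, size=(8, 3)) + np.array([0.0, 1.0, 0.5])
        per_animal = {
            f"a{i}": {f"c{j}": data[i, j] for j in range(3)} for i in range(8)
        }
        res = run_rm_comparison(per_animal)
        long = pd.DataFrame(
            [(f"a{i}", f"c{j}", data[i, j]) for i in range(8) for j in range(3)],
            columns=["subj", "cond", "y"],
        )
        aov = pg.rm_anova(data=long, dv="y", within="cond", subject="subj")
        assert res.statistic == pytest.approx(float(aov["F"].iloc[0]), rel=1e-9)
        assert res.p == pytest.approx(float(aov["p_unc"].iloc[0]), rel=1e-9)

    def test_incomplete_animal_excluded_with_note(self):
        per_animal = {
            "a1": {"c1": 1.0, "c2": 2.0},
            "a2": {"c1": 1.5, "c2": 2.5},
            "a3": {"c1": 1.2, "c2": 2.2},
            "broken": {"c1": 9.0},
        }
        res = run_rm_comparison(per_animal)
        assert any("broken" in n for n in res.notes)
        assert res.df_residual == 2  # 3 complete animals, 2 conditions

    def test_too_few_complete_animals_rejected(self):
        with pytest.raises(ValueError, match="complete animals"):
            run_rm_comparison({"a1": {"c1": 1.0, "c2": 2.0}, "a2": {"c1": 1.0}})

    def test_log_transform_on_positive_skewed(self):
        rng = np.random.default_rng(8)
        data = np.exp(rng.normal(0, 1.5, size=(10, 3)))
        per_animal = {
            f"a{i}": {f"c{j}": data[i, j] for j in range(3)} for i in range(10)
        }
        res = run_rm_comparison(per_animal)
        if not res.normality_pass:
            assert res.transform in ("none", "log")
        else:
            # transform applied only when it repairs the checks
            assert res.transform == "log" or res.normality_pass
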