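"""Statistics pipeline: normality gate, group tests, correlations, stepwise."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from hemoshear.stats import (
    DegenerateSampleError,
    backward_stepwise_logistic,
    build_comparison_tables,
    compare_groups,
    spearman_matrix,
    univariate_screen,
)
from hemoshear.stats import test_normality as normality_p  # avoid test collection


class TestNormality:
    def test_normal_sample_passes_gate(self):
        rng = np.random.default_rng(0)
        hits = sum(
            normality_p(rng.normal(size=500)) >= 0.05 for _ in range(100)
        )
        # ~5% nominal false-positive rate at the 0.05 gate
        assert hits >= 88

    def test_lognormal_sample_fails_gate(self):
        rng = np.random.default_rng(1)
        hits = sum(
            normality_p(rng.lognormal(0.0, 1.0, size=500)) < 0.05
            for _ in range(50)
        )
        assert hits == 50

    def test_constant_sample_raises(self):
        with pytest.raises(DegenerateSampleError):
            normality_p(np.full(20, 3.0))

    def test_tiny_sample_raises(self):
        with pytest.raises(DegenerateSampleError):
            normality_p([1.0, 2.0, 3.0])


def exact_mann_whitney_oracle(a, b):
    """Exhaustive enumeration of U and the exact two-sided p."""
    a, b = list(a), list(b)
    n1 = len(a)
    pooled = a + b
    u_obs = sum(1 for x in a for y in b if x > y) + 0.5 * sum(
        1 for x in a for y in b if x == y
    )
    n = len(pooled)
    us = []
    for idx in itertools.combinations(range(n), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(n) if i not in idx]
        us.append(
            sum(1 for x in ga for y in gb if x > y)
            + 0.5 * sum(1 for x in ga for y in gb if x == y)
        )
    us = np.array(us)
    mu = n1 * (n - n1) / 2.0
    p = np.mean(np.abs(us - mu) >= abs(u_obs - mu) - 1e-12)
    return u_obs, p


class TestCompareGroups:
    def test_identical_samples(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        r = compare_groups(a, a)
        assert r.statistic == 0.0
        assert r.p_two_sided == 1.0

    def test_disjoint_triples_exact_mann_whitney(self):
        r = compare_groups([1, 2, 3], [4, 5, 6], force_test="mann_whitney")
        assert r.test_used == "mann_whitney"
        assert r.statistic == 0.0
        assert r.p_two_sided == pytest.approx(0.1)

    @pytest.mark.parametrize("n1,n2", [(3, 3), (3, 4), (4, 4), (4, 5), (5, 5), (3, 7)])
    def test_mann_whitney_matches_enumeration_oracle(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(20):
            x = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            a, b = x[:n1], x[n1:]
            r = compare_groups(a, b, force_test="mann_whitney")
            u_o, p_o = exact_mann_whitney_oracle(a, b)
            # scipy reports U of the first sample; enumeration likewise
            assert r.statistic == pytest.approx(u_o)
            assert r.p_two_sided == pytest.approx(p_o, abs=1e-12)

    def test_swapping_groups_flips_t_statistic(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 30)
        r1 = compare_groups(a, b, force_test="t")
        r2 = compare_groups(b, a, force_test="t")
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_two_sided == pytest.approx(r2.p_two_sided)

    def test_descriptives_match_test_choice(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=40), rng.normal(size=40)
        r = compare_groups(a, b)
        key = "mean" if r.test_used == "t" else "median"
        assert key in r.descriptives[0]

    def test_skewed_samples_routed_to_mann_whitney(self):
        rng = np.random.default_rng(4)
        a = rng.lognormal(0, 1.5, size=200)
        b = rng.lognormal(0.3, 1.5, size=200)
        r = compare_groups(a, b)
        assert r.test_used == "mann_whitney"
        assert "q1" in r.descriptives[0]


class TestSpearman:
    def test_perfect_monotone(self):
        f = pd.DataFrame({"h": np.arange(10.0), "m": np.arange(10.0) ** 3})
        r = spearman_matrix(f, ["h"], ["m"]).iloc[0]
        assert r["r"] == pytest.approx(1.0)

    def test_perfect_antitone(self):
        f = pd.DataFrame({"h": np.arange(10.0), "m": -np.arange(10.0)})
        assert spearman_matrix(f, ["h"], ["m"]).iloc[0]["r"] == pytest.approx(-1.0)

    def test_ties_match_rank_formula_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 3.0, 3.0, 5.0, 4.0, 6.0, 7.0])
        f = pd.DataFrame({"h": x, "m": y})
        r = spearman_matrix(f, ["h"], ["m"]).iloc[0]["r"]
        rx = pd.Series(x).rank().to_numpy()
        ry = pd.Series(y).rank().to_numpy()
        oracle = np.corrcoef(rx, ry)[0, 1]  # Pearson on mid-ranks
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        f1 = pd.DataFrame({"h": x, "m": y})
        f2 = pd.DataFrame({"h": np.exp(x), "m": y**3})
        r1 = spearman_matrix(f1, ["h"], ["m"]).iloc[0]["r"]
        r2 = spearman_matrix(f2, ["h"], ["m"]).iloc[0]["r"]
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_constant_column_flagged(self):
        f = pd.DataFrame({"h": np.ones(10), "m": np.arange(10.0)})
        row = spearman_matrix(f, ["h"], ["m"]).iloc[0]
        assert row["undefined"]
        assert math.isnan(row["r"])


class TestScreenAndStepwise:
    @staticmethod
    def _frame(rng, n=60, signal=0.0):
        x = rng.normal(size=(n, 4))
        logits = signal * x[:, 0]
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-logits))).astype(int)
        f = pd.DataFrame(x, columns=["s", "n1", "n2", "n3"])
        f["ruptured"] = y
        return f

    def test_strong_predictor_screened(self):
        rng = np.random.default_rng(6)
        n = 30
        f = pd.DataFrame({
            "big": np.concatenate([rng.normal(0, 1, n), rng.normal(3, 1, n)]),
            "null": rng.normal(size=2 * n),
            "ruptured": np.r_[np.zeros(n, int), np.ones(n, int)],
        })
        assert "big" in univariate_screen(f, ["big", "null"])

    def test_null_screen_rate_near_alpha(self):
        rng = np.random.default_rng(7)
        picked = 0
        total = 0
        for _ in range(150):
            f = self._frame(rng)
            picked += len(univariate_screen(f, ["s", "n1", "n2", "n3"]))
            total += 4
        rate = picked / total
        assert 0.02 < rate < 0.09  # ~0.05 expected under the null

    def test_single_strong_predictor_recovered(self):
        rng = np.random.default_rng(8)
        n = 200
        x = rng.normal(size=n)
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-2 * x))).astype(int)
        f = pd.DataFrame({"s": x, "ruptured": y})
        fit = backward_stepwise_logistic(f, ["s"])
        assert fit.retained == ("s",)
        import statsmodels.api as sm
        ref = sm.Logit(y, sm.add_constant(x[:, None])).fit(disp=0)
        lo, hi = ref.conf_int()[1]
        assert lo <= fit.coefficients["s"] <= hi
        assert lo <= 2.0 <= hi  # truth in its own 95% CI for this seed

    def test_noise_removed_before_signal(self):
        rng = np.random.default_rng(9)
        ok = 0
        for _ in range(30):
            f = self._frame(rng, n=200, signal=2.0)
            fit = backward_stepwise_logistic(f, ["s", "n1", "n2", "n3"])
            if "s" in fit.retained and all(x[1] != "s" for x in fit.trace[:-1]):
                ok += 1
        assert ok >= 27

    def test_pure_noise_may_empty_model_with_full_trace(self):
        rng = np.random.default_rng(10)
        f = self._frame(rng, n=120, signal=0.0)
        fit = backward_stepwise_logistic(f, ["n1", "n2", "n3"])
        assert len(fit.trace) == 3 - len(fit.retained)
        for k, (step, name, p) in enumerate(fit.trace, start=1):
            assert step == k
            assert p > 0.10

    def test_trace_replay_reproduces_final_model(self):
        rng = np.random.default_rng(11)
        f = self._frame(rng, n=150, signal=1.5)
        fit = backward_stepwise_logistic(f, ["s", "n1", "n2", "n3"])
        remaining = [c for c in ["s", "n1", "n2", "n3"]]
        for _, removed, _ in fit.trace:
            remaining.remove(removed)
        assert tuple(remaining) == fit.retained
        if fit.retained:
            import statsmodels.api as sm
            X = sm.add_constant(f[list(fit.retained)].to_numpy())
            ref = sm.Logit(f["ruptured"].to_numpy(float), X).fit(disp=0, maxiter=200)
            names = ["const"] + list(fit.retained)
            for n_, c_ in zip(names, ref.params):
                assert fit.coefficients[n_] == c_  # bit-for-bit replay

    def test_separation_flagged_not_raised(self):
        f = pd.DataFrame({
            "s": np.r_[np.zeros(10), np.ones(10)],
            "ruptured": np.r_[np.zeros(10, int), np.ones(10, int)],
        })
        fit = backward_stepwise_logistic(f, ["s"])
        assert fit.separation_flagged


class TestComparisonTables:
    @staticmethod
    def _cohort(rng, n=20, shift=0.0):
        rows = []
        for lab in ("ruptured", "unruptured"):
            for cat in ("narrow", "wide"):
                mu = 3.0 + (shift if lab == "ruptured" else 0.0)
                for _ in range(n):
                    rows.append({
                        "rupture_label": lab, "neck_category": cat,
                        "MWSS": rng.normal(mu, 1.0), "PWSS": rng.normal(7, 1),
                        "LSAR": rng.uniform(0, 1), "HWSS": rng.normal(9, 2),
                        "MP_ratio": rng.normal(0.5, 0.1), "HP_ratio": rng.normal(1.3, 0.2),
                    })
        return pd.DataFrame(rows)

    def test_four_tables_emitted(self):
        f = self._cohort(np.random.default_rng(12))
        t = build_comparison_tables(f)
        assert set(t) == {"overall", "by_neck", "narrow", "wide"}
        assert list(t["overall"]["parameter"]) == [
            "MWSS", "PWSS", "LSAR", "HWSS", "MP_ratio", "HP_ratio"
        ]

    def test_shifted_metric_flagged_significant(self):
        f = self._cohort(np.random.default_rng(13), shift=2.0)
        t = build_comparison_tables(f)["overall"]
        assert float(t.loc[t["parameter"] == "MWSS", "p"].iloc[0]) < 0.01

    def test_null_cohort_not_overflagged(self):
        rng = np.random.default_rng(14)
        sig = 0
        for _ in range(20):
            t = build_comparison_tables(self._cohort(rng))["overall"]
            sig += int((t["p"] < 0.05).sum())
        assert sig <= 0.05 * 20 * 6 + 2 * math.sqrt(0.05 * 0.95 * 20 * 6) + 1

    def test_single_stratum_skips_stratified_tables(self):
        f = self._cohort(np.random.default_rng(15))
        f = f[f["neck_category"] == "narrow"]
        t = build_comparison_tables(f)
        assert "wide" not in t
        assert "by_neck" not in t
        assert "overall" in t
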