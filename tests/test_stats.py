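"""Cohort statistics: tests against oracles and closed forms."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from flow4d import stats as st
from flow4d.synthetic import make_regression_design


def two_group_frame(a, b):
    return pd.DataFrame({
        "group": ["control"] * len(a) + ["PAH"] * len(b),
        "v": np.concatenate([a, b]),
    })


class TestGroupCompare:
    def test_family_alpha_printed_value(self):
        # CPET family of 3: 0.05/3 reported as 0.017 at 3 decimals
        assert round(st.bonferroni_alpha(3), 3) == 0.017

    def test_normal_data_uses_t(self):
        rng = np.random.default_rng(0)
        gc = st.group_compare(two_group_frame(rng.normal(0, 1, 40),
                                              rng.normal(0.2, 1, 40)), "v")
        assert gc.test == "t"

    def test_skewed_data_uses_mannwhitney(self):
        rng = np.random.default_rng(1)
        gc = st.group_compare(two_group_frame(rng.lognormal(0, 1.2, 40),
                                              rng.lognormal(0.3, 1.2, 40)), "v")
        assert gc.test == "mannwhitney"

    def test_type_i_rate_near_nominal(self):
        # identical distributions: ~5% rejections at alpha 0.05
        rng = np.random.default_rng(7)
        rej = 0
        n_sim = 400
        for _ in range(n_sim):
            gc = st.group_compare(two_group_frame(rng.normal(size=50),
                                                  rng.normal(size=50)), "v")
            rej += gc.p_value < 0.05
        assert abs(rej / n_sim - 0.05) < 0.03

    def test_power_for_1sd_shift(self):
        rng = np.random.default_rng(3)
        rej = 0
        for _ in range(200):
            gc = st.group_compare(two_group_frame(rng.normal(0, 1, 45),
                                                  rng.normal(1.0, 1, 51)), "v")
            rej += gc.p_value < 0.05
        assert rej / 200 > 0.99

    def test_two_groups_required(self):
        df = pd.DataFrame({"group": ["a"] * 5, "v": np.arange(5.0)})
        with pytest.raises(ValueError, match="two groups"):
            st.group_compare(df, "v")


class TestCorrelate:
    def test_perfect_linear(self):
        df = pd.DataFrame({"x": np.arange(10.0)})
        df["y"] = 2 * df["x"]
        r, p = st.correlate(df, "x", "y")
        assert r == pytest.approx(1.0)

    def test_orthogonalized_zero(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        xc = x - x.mean()
        y = y - xc * np.dot(xc, y) / np.dot(xc, xc)  # centered orthogonalization
        r, _ = st.correlate(pd.DataFrame({"x": x, "y": y}), "x", "y")
        assert abs(r) < 1e-12

    def test_planted_correlation_recovered(self):
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(100):
            z = rng.standard_normal((96, 2))
            x = z[:, 0]
            y = -0.6 * x + np.sqrt(1 - 0.36) * z[:, 1]
            r, _ = st.correlate(pd.DataFrame({"x": x, "y": y}), "x", "y")
            hits += abs(r - (-0.6)) < 0.15
        assert hits >= 90


class TestStepwise:
    def test_identity_candidate(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"y": rng.normal(size=30)})
        df["x"] = df["y"]
        rep = st.stepwise_model(df, "y", ["x"])
        assert rep.r_squared == pytest.approx(1.0)
        assert rep.selected.loc["x", "coef"] == pytest.approx(1.0)

    def test_planted_support_recovered(self):
        hits = 0
        for s in range(60):
            df = make_regression_design(seed=s)
            rep = st.stepwise_model(df, "y", [c for c in df.columns if c != "y"])
            hits += set(rep.selected.index) == {"x1", "x2"}
        assert hits / 60 >= 0.85

    def test_pure_noise_selection_near_screen_level(self):
        rng = np.random.default_rng(21)
        picked = 0
        total = 0
        for _ in range(150):
            X = rng.standard_normal((96, 5))
            df = pd.DataFrame(X, columns=[f"d{i}" for i in range(5)])
            df["y"] = rng.standard_normal(96)
            rep = st.stepwise_model(df, "y", [f"d{i}" for i in range(5)])
            picked += len(rep.selected)
            total += 5
        assert picked / total < 0.08  # at most ~the screen level

    def test_ln_outcome_requires_positive(self):
        df = pd.DataFrame({"y": [-1.0, 2.0, 3.0], "x": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="positive"):
            st.stepwise_model(df, "y", ["x"], ln_outcome=True)

    def test_ln_outcome_log_linear_exact(self):
        x = np.linspace(0.1, 2, 40)
        df = pd.DataFrame({"x": x, "y": np.exp(1.0 + 0.5 * x)})
        rep = st.stepwise_model(df, "y", ["x"], ln_outcome=True)
        assert rep.selected.loc["x", "coef"] == pytest.approx(0.5, rel=1e-9)


class TestROCYouden:
    def test_perfect_separation(self):
        df = pd.DataFrame({"s": [1, 2, 3, 10, 11, 12], "y": [0, 0, 0, 1, 1, 1]})
        rep = st.roc_youden(df, "s", "y")
        assert rep.auc == 1.0
        assert rep.youden == 1.0
        assert 3 < rep.threshold <= 10

    def test_auc_equals_scaled_mannwhitney(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            n1, n0 = rng.integers(5, 30, 2)
            s = rng.normal(size=n1 + n0)
            y = np.r_[np.ones(n1, int), np.zeros(n0, int)]
            df = pd.DataFrame({"s": s, "y": y})
            rep = st.roc_youden(df, "s", "y", direction="greater")
            u = sps.mannwhitneyu(s[y == 1], s[y == 0]).statistic
            assert rep.auc == pytest.approx(u / (n1 * n0), abs=1e-12)

    def test_threshold_matches_bruteforce_enumeration(self):
        # exhaustive oracle over all cut-points on many 6-observation tables
        rng = np.random.default_rng(17)
        for _ in range(200):
            s = np.round(rng.normal(size=6), 2)
            y = rng.permutation([0, 0, 0, 1, 1, 1])
            df = pd.DataFrame({"s": s, "y": y})
            rep = st.roc_youden(df, "s", "y", direction="greater")
            best = None
            for thr in np.unique(s):
                pred = s >= thr
                sens = np.mean(pred[y == 1])
                spec = np.mean(~pred[y == 0])
                key = (sens + spec - 1, spec, thr)
                if best is None or key > best:
                    best = key
            assert rep.threshold == pytest.approx(best[2])
            assert rep.youden == pytest.approx(best[0])

    def test_null_auc_near_half(self):
        # label-independent predictor: AUC ~ 0.5 with the Mann-Whitney
        # null SD sqrt((n+1)/(12 n1 n0)); ~95% of seeds inside 1.96 SD
        n1, n0 = 45, 51
        sd = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
        rng = np.random.default_rng(19)
        hits = 0
        for _ in range(200):
            df = pd.DataFrame({"s": rng.normal(size=96),
                               "y": np.r_[np.ones(n1, int), np.zeros(n0, int)]})
            rep = st.roc_youden(df, "s", "y", direction="greater")
            hits += abs(rep.auc - 0.5) < 1.96 * sd
        assert hits / 200 > 0.90

    def test_single_class_rejected(self):
        df = pd.DataFrame({"s": [1.0, 2.0], "y": [1, 1]})
        with pytest.raises(ValueError, match="both classes"):
            st.roc_youden(df, "s", "y")


class TestDeLong:
    def test_identical_predictors(self):
        rng = np.random.default_rng(23)
        df = pd.DataFrame({"a": rng.normal(size=40),
                           "y": np.r_[np.ones(20, int), np.zeros(20, int)]})
        df["b"] = df["a"]
        auc_a, auc_b, z, p = st.delong_compare(df, "a", "b", "y")
        assert auc_a == auc_b
        assert z == 0.0 and p == 1.0

    def test_reduces_to_single_auc_variance(self):
        # coincident predictors: covariance matrix entries all equal the
        # single-AUC DeLong variance
        rng = np.random.default_rng(29)
        s = rng.normal(size=60)
        y = np.r_[np.ones(25, int), np.zeros(35, int)]
        v = st.delong_variance(s, y)
        auc_a, auc_b, cov = st._delong_structural(s[y == 1], s[y == 0],
                                                  s[y == 1], s[y == 0])
        assert cov[0, 0] == pytest.approx(v)
        assert cov[0, 1] == pytest.approx(v)

    def test_agrees_with_paired_bootstrap_small(self):
        rng = np.random.default_rng(31)
        n = 12
        y = np.r_[np.ones(6, int), np.zeros(6, int)]
        a = rng.normal(size=n) + y
        b = rng.normal(size=n)
        df = pd.DataFrame({"a": a, "b": b, "y": y})
        auc_a, auc_b, z, p = st.delong_compare(df, "a", "b", "y")
        # paired bootstrap of the AUC difference
        diffs = []
        for _ in range(2000):
            idx = np.r_[rng.choice(np.flatnonzero(y == 1), 6),
                        rng.choice(np.flatnonzero(y == 0), 6)]
            diffs.append(st._auc_mwu(a[idx], y[idx]) - st._auc_mwu(b[idx], y[idx]))
        boot_z = (auc_a - auc_b) / np.std(diffs, ddof=1)
        # same order of evidence within Monte-Carlo slack
        assert np.sign(boot_z) == np.sign(z)
        assert abs(abs(z) - abs(boot_z)) < 1.0

    def test_constant_predictor_rejected(self):
        df = pd.DataFrame({"a": np.ones(10), "b": np.arange(10.0),
                           "y": [0, 1] * 5})
        with pytest.raises(ValueError, match="constant"):
            st.delong_compare(df, "a", "b", "y")


class TestNestedLogistic:
    def test_duplicate_variable_adds_nothing(self):
        rng = np.random.default_rng(37)
        y = np.r_[np.ones(30, int), np.zeros(30, int)]
        x = rng.normal(size=60) + 0.8 * y
        df = pd.DataFrame({"y": y, "x": x, "x2": x})
        res = st.nested_logistic(df, "y", ["x"], "x2")
        assert res["delta_chi2"] == pytest.approx(0.0, abs=1e-5)
        assert res["p"] > 0.99

    def test_informative_added_var(self):
        rng = np.random.default_rng(41)
        big = 0
        for s in range(40):
            r = np.random.default_rng(s)
            y = np.r_[np.ones(48, int), np.zeros(48, int)]
            base = r.normal(size=96) + 0.3 * y
            add = r.normal(size=96) + 1.5 * y
            df = pd.DataFrame({"y": y, "b": base, "a": add})
            big += st.nested_logistic(df, "y", ["b"], "a")["delta_chi2"] > 10
        assert big / 40 >= 0.95

    def test_affine_invariance(self):
        rng = np.random.default_rng(43)
        y = np.r_[np.ones(40, int), np.zeros(40, int)]
        b = rng.normal(size=80)
        a = rng.normal(size=80) + 0.5 * y
        df1 = pd.DataFrame({"y": y, "b": b, "a": a})
        df2 = pd.DataFrame({"y": y, "b": 3 * b - 7, "a": 0.1 * a + 2})
        r1 = st.nested_logistic(df1, "y", ["b"], "a")
        r2 = st.nested_logistic(df2, "y", ["b"], "a")
        assert r1["delta_chi2"] == pytest.approx(r2["delta_chi2"], abs=1e-6)

    def test_null_delta_chi2_is_chi2_1(self):
        # added pure-noise variable: increments follow chi2(1)
        deltas = []
        for s in range(300):
            r = np.random.default_rng(10_000 + s)
            y = np.r_[np.ones(48, int), np.zeros(48, int)]
            df = pd.DataFrame({"y": y, "b": r.normal(size=96) + 0.5 * y,
                               "a": r.normal(size=96)})
            deltas.append(st.nested_logistic(df, "y", ["b"], "a")["delta_chi2"])
        ks = sps.kstest(deltas, sps.chi2(1).cdf)
        assert ks.pvalue > 0.01


class TestBlandAltman:
    def test_identical_pairs(self):
        res = st.bland_altman(np.c_[np.arange(1, 6.0), np.arange(1, 6.0)])
        assert res["bias"] == 0 and res["loa_low"] == 0 and res["loa_high"] == 0
        assert res["cov_pct"] == 0

    def test_constant_offset(self):
        a = np.arange(1, 6.0)
        res = st.bland_altman(np.c_[a + 2.0, a])
        assert res["bias"] == pytest.approx(2.0)
        assert res["sd_diff"] == 0

    def test_noise_sd_closed_form(self):
        # independent noise sigma on both arms: SD(diff) ~ sigma * sqrt(2)
        rng = np.random.default_rng(47)
        sigma = 0.8
        truth = rng.uniform(10, 20, 4000)
        pairs = np.c_[truth + rng.normal(0, sigma, 4000),
                      truth + rng.normal(0, sigma, 4000)]
        res = st.bland_altman(pairs)
        assert res["sd_diff"] == pytest.approx(sigma * np.sqrt(2), rel=0.05)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            st.bland_altman([[1.0, 2.0]])
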