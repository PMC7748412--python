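"""Statistical battery: K-S, Spearman, log-normal fits, Tukey, summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from spinemorph.stats import (fit_lognormal, ks_two_sample, linear_r2,
                              spearman, summarize_condition,
                              tukey_er_comparison)


class TestKS:
    def test_identical_samples(self):
        x = np.array([1.0, 2, 3, 4, 5])
        g = ks_two_sample(x, x.copy())
        assert g.ks_d == 0.0
        assert g.ks_p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        g = ks_two_sample(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert g.ks_d == 1.0
        assert g.ks_p < 0.2

    def test_summary_fields(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 50), rng.normal(1, 1, 60)
        g = ks_two_sample(x, y, labels=("a", "b"))
        assert g.n == (50, 60)
        assert g.means[1] > g.means[0]
        assert 0 <= g.ks_d <= 1 and 0 <= g.ks_p <= 1

    def test_null_calibration_reduced(self):
        # ~5% rejections under the null (reduced replicate count)
        rng = np.random.default_rng(42)
        rej = sum(
            ks_two_sample(rng.lognormal(0, 0.5, 80),
                          rng.lognormal(0, 0.5, 80)).ks_p < 0.05
            for _ in range(300))
        assert 0.01 <= rej / 300 <= 0.10

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample(np.array([1.0]), np.array([1.0, 2.0]))


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.array([1.0, 2, 3, 4, 5])
        r = spearman(x, np.exp(x))
        assert r.rho == pytest.approx(1.0)

    def test_exact_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            x = rng.normal(size=5)
            y = rng.normal(size=5)
            res = spearman(x, y)
            rx, ry = sps.rankdata(x), sps.rankdata(y)
            obs = abs(sps.pearsonr(rx, ry).statistic)
            hits = sum(abs(sps.pearsonr(rx, np.asarray(p)).statistic)
                       >= obs - 1e-12
                       for p in itertools.permutations(ry))
            assert res.p == pytest.approx(hits / 120, abs=1e-12)

    def test_constant_input_flagged(self):
        r = spearman(np.ones(5), np.arange(5.0))
        assert np.isnan(r.rho)
        assert "constant_input" in r.flags

    def test_large_sample_t_approximation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        y = 0.4 * x + rng.normal(size=200)
        r = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert r.rho == pytest.approx(ref.statistic)
        assert r.p == pytest.approx(ref.pvalue)
        assert r.p < 1e-6


class TestLognormalFit:
    def test_self_consistency_r2(self):
        rng = np.random.default_rng(7)
        x = rng.lognormal(-2.0, 0.5, 10_000)
        fit = fit_lognormal(x)
        assert fit.r_squared > 0.95

    def test_parameter_recovery_within_3se(self):
        rng = np.random.default_rng(8)
        n, mu, sig = 5000, -2.0, 0.5
        fit = fit_lognormal(rng.lognormal(mu, sig, n))
        assert abs(fit.log_mean - mu) < 3 * sig / np.sqrt(n)
        assert abs(fit.log_sd - sig) < 3 * sig / np.sqrt(2 * n)

    def test_uniform_data_fits_worse_than_lognormal_data(self):
        rng = np.random.default_rng(9)
        uni = rng.uniform(1.0, 2.0, 2000)
        logn = rng.lognormal(np.log(1.5), 0.2, 2000)
        assert fit_lognormal(uni).r_squared < fit_lognormal(logn).r_squared

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            fit_lognormal(np.array([1.0, -1.0] + [1.0] * 10))


class TestLinearR2:
    def test_exact_line(self):
        x = np.arange(10.0)
        assert linear_r2(x, 3 * x - 1) == pytest.approx(1.0)

    def test_independent_pair_near_zero(self):
        rng = np.random.default_rng(11)
        assert linear_r2(rng.normal(size=3000), rng.normal(size=3000)) < 0.01

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            linear_r2(np.ones(5), np.arange(5.0))


def _er_frame(rng, n_per_group=30, effect=0.0):
    rows = []
    for cond in ("cryo", "chemical"):
        for er in (False, True):
            v = rng.lognormal(-2.7 + (effect if er else 0.0), 0.6,
                              n_per_group)
            rows += [{"condition": cond, "er_in_neck": er, "head_volume": x}
                     for x in v]
    return pd.DataFrame(rows)


class TestTukey:
    def test_identical_groups_all_p_near_one(self):
        rng = np.random.default_rng(12)
        base = rng.normal(0, 1, 25)
        df = pd.DataFrame(
            [{"condition": c, "er_in_neck": e, "head_volume": x}
             for c in ("cryo", "chemical") for e in (False, True)
             for x in base])
        t = tukey_er_comparison(df, "head_volume")
        assert (t.p_adj > 0.99).all()

    def test_er_effect_detected_within_conditions(self):
        rng = np.random.default_rng(13)
        t = tukey_er_comparison(_er_frame(rng, effect=0.7), "head_volume")
        within = t[t.within_condition]
        assert (within.p_adj < 0.01).all()

    def test_adjusted_p_dominates_pairwise_t(self):
        rng = np.random.default_rng(14)
        df = _er_frame(rng, effect=0.25)
        t = tukey_er_comparison(df, "head_volume")
        groups = {f"{c}{'+ER' if e else '-ER'}":
                  df[(df.condition == c) & (df.er_in_neck == e)]
                  .head_volume.to_numpy()
                  for c in ("chemical", "cryo") for e in (False, True)}
        for _, row in t.iterrows():
            p_t = sps.ttest_ind(groups[row.group_a], groups[row.group_b]).pvalue
            assert row.p_adj >= p_t - 1e-9

    def test_empty_group_rejected(self):
        df = pd.DataFrame({"condition": ["cryo"] * 4,
                           "er_in_neck": [False] * 4,
                           "head_volume": [1.0, 2, 3, 4]})
        with pytest.raises(ValueError):
            tukey_er_comparison(df, "head_volume")


class TestSummaries:
    def test_single_record(self):
        df = pd.DataFrame({"condition": ["cryo"], "neck_length": [0.7]})
        s = summarize_condition(df, ["neck_length"])
        assert s.iloc[0]["mean"] == 0.7
        assert np.isnan(s.iloc[0]["sd"])

    def test_order_invariance(self):
        rng = np.random.default_rng(15)
        df = pd.DataFrame({
            "condition": ["cryo"] * 40 + ["chemical"] * 40,
            "neck_length": rng.lognormal(-0.4, 0.6, 80)})
        a = summarize_condition(df, ["neck_length"])
        b = summarize_condition(df.sample(frac=1.0, random_state=1),
                                ["neck_length"])
        pd.testing.assert_frame_equal(a.reset_index(drop=True),
                                      b.reset_index(drop=True))
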