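"""Cluster-aware inference: signed-rank, correlation, mixed model,
distribution summaries, multiplicity."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ablaq.stats import (
    adjust_pvalues,
    clustered_correlation,
    clustered_signed_rank,
    distribution_summary,
    fit_discrepancy_model,
)


class TestClusteredSignedRank:
    def test_singleton_clusters_match_classical_wilcoxon(self, rng):
        """With one observation per cluster the statistic reduces exactly to
        the classical signed-rank normal approximation."""
        d = rng.normal(0.4, 1.0, 30)
        res = clustered_signed_rank(d, np.arange(len(d)), compute_ci=False)
        ref = sps.wilcoxon(d, correction=False, method="approx")
        assert res.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_matches_cluster_signflip_permutation_null(self):
        """The analytic p tracks the exact cluster-level sign-flip null.

        2^12 = 4096 flip patterns give the permutation p enough resolution
        to test the normal approximation meaningfully."""
        rng = np.random.default_rng(31)
        gaps = []
        for _ in range(20):
            n_cl = 12
            cl = np.sort(np.concatenate(
                [np.arange(n_cl), rng.integers(0, n_cl, 14)]))
            d = rng.normal(rng.uniform(-0.8, 0.8), 1.0, len(cl))
            res = clustered_signed_rank(d, cl, compute_ci=False)
            s = np.sign(d) * sps.rankdata(np.abs(d))
            S = np.array([s[cl == c].sum() for c in range(n_cl)])
            signs = np.array(list(itertools.product([1, -1], repeat=n_cl)))
            Ts = np.abs(signs @ S)
            p_perm = float(np.mean(Ts >= abs(s.sum()) - 1e-9))
            gaps.append(abs(res.p - p_perm))
        assert np.median(gaps) <= 0.02
        assert max(gaps) <= 0.1

    def test_type_one_error_under_clustered_null(self):
        """Symmetric differences in clusters of two: rejection at alpha=0.05
        stays near nominal over 2,000 replicates."""
        rng = np.random.default_rng(42)
        rej = 0
        n_rep = 2000
        for _ in range(n_rep):
            vals = rng.normal(0, 1, (20, 2))
            r = clustered_signed_rank(
                vals.ravel(), np.repeat(np.arange(20), 2), compute_ci=False)
            rej += r.p < 0.05
        assert 0.03 <= rej / n_rep <= 0.07

    def test_invariant_to_order_and_relabeling(self, rng):
        d = rng.normal(0.3, 1, 18)
        cl = rng.integers(0, 6, 18)
        res1 = clustered_signed_rank(d, cl)
        perm = rng.permutation(18)
        relabel = np.array(["abcdef"[c] for c in cl])
        res2 = clustered_signed_rank(d[perm], relabel[perm])
        assert res1.statistic == pytest.approx(res2.statistic, abs=1e-12)
        assert res1.ci_low == pytest.approx(res2.ci_low, abs=1e-9)

    def test_ci_covers_location_shift(self, rng):
        d = rng.normal(2.0, 1.0, 40)
        cl = rng.integers(0, 25, 40)
        res = clustered_signed_rank(d, cl)
        assert res.ci_low < 2.0 < res.ci_high
        assert res.p < 0.001

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="zero"):
            clustered_signed_rank(np.zeros(5), np.arange(5))
        with pytest.raises(ValueError, match="clusters"):
            clustered_signed_rank(np.ones(5), np.zeros(5))


class TestClusteredCorrelation:
    def test_perfect_correlation(self, rng):
        x = rng.normal(size=80)
        r = clustered_correlation(x, x, rng.integers(0, 50, 80), n_boot=400, seed=0)
        assert r.r == pytest.approx(1.0)
        assert r.p < 0.01

    def test_null_rejection_rate_near_nominal(self):
        rng = np.random.default_rng(7)
        rej = 0
        n_sim = 500
        for i in range(n_sim):
            sizes = rng.integers(1, 4, 100)
            cl = np.repeat(np.arange(100), sizes)
            n = len(cl)
            rr = clustered_correlation(
                rng.normal(size=n), rng.normal(size=n), cl,
                n_boot=1000, seed=int(rng.integers(2**31)))
            rej += rr.p < 0.05
        assert 0.03 <= rej / n_sim <= 0.07

    def test_duplicating_clusters_does_not_shrink_ci(self, rng):
        """Copying every cluster's rows must not tighten inference much —
        the bootstrap resamples clusters, not rows."""
        n = 60
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        cl = np.arange(n) // 2
        r1 = clustered_correlation(x, y, cl, n_boot=2000, seed=3)
        x2, y2, cl2 = np.tile(x, 2), np.tile(y, 2), np.tile(cl, 2)
        r2 = clustered_correlation(x2, y2, cl2, n_boot=2000, seed=3)
        w1 = r1.ci_high - r1.ci_low
        w2 = r2.ci_high - r2.ci_low
        assert w2 > 0.9 * w1

    def test_spearman_variant(self, rng):
        x = rng.normal(size=50)
        y = np.exp(x)  # monotone, nonlinear
        r = clustered_correlation(x, y, np.arange(50), method="spearman",
                                  n_boot=300, seed=1)
        assert r.r == pytest.approx(1.0)

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(ValueError, match="variance"):
            clustered_correlation(np.ones(10), rng.normal(size=10), np.arange(10))


class TestDiscrepancyModel:
    @staticmethod
    def make_cohort(rng, n_pat=60, intercept=0.0, sigma_u=0.2, sigma_e=0.4,
                    singletons=False):
        rows = []
        aid = 0
        for p in range(n_pat):
            n_abl = 1 if singletons else rng.choice([1, 2, 3], p=[0.7, 0.25, 0.05])
            u = 0.0 if singletons else rng.normal(0, sigma_u)
            for _ in range(n_abl):
                vendor = rng.choice([3.5, 5.8, 6.8, 7.8])
                y = intercept + u + rng.normal(0, sigma_e)
                rows.append({
                    "patient_id": f"P{p}",
                    "volume_cm3": vendor * np.exp(y),
                    "vendor_volume_cm3": vendor,
                    "tip_to_edge_mm": 6.0 * np.exp(y),
                    "vendor_tip_to_edge_mm": 6.0,
                    "contraction_mm": rng.normal(2.5, 1.5),
                    "followup_days": rng.normal(30, 8),
                    "tumor_volume_mm3": rng.lognormal(5.7, 0.8),
                    "energy_wmin": rng.choice([130.0, 260.0, 325.0, 390.0]),
                })
                aid += 1
        return pd.DataFrame(rows)

    def test_injected_intercept_recovered(self):
        """An injected ln(2) residual discrepancy is recovered: the intercept
        CI covers 2, and the precisely estimable quantity — the fitted
        discrepancy at the covariate means — lands close to 2."""
        rng = np.random.default_rng(11)
        df = self.make_cohort(rng, n_pat=110, intercept=np.log(2.0))
        res = fit_discrepancy_model(df, "volume")
        inter = res[res["term"] == "Intercept"].iloc[0]
        assert inter["ci_low"] <= 2.0 <= inter["ci_high"]
        coefs = np.log(res["effect_size"].to_numpy())
        means = np.array([1.0, df["followup_days"].mean(),
                          df["contraction_mm"].mean(),
                          np.log(df["tumor_volume_mm3"]).mean(),
                          np.log(df["energy_wmin"]).mean()])
        assert 1.6 <= np.exp(coefs @ means) <= 2.5

    def test_singleton_patients_match_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        df = self.make_cohort(rng, n_pat=80, singletons=True)
        res = fit_discrepancy_model(df, "volume")
        X = sm.add_constant(np.column_stack([
            df["followup_days"], df["contraction_mm"],
            np.log(df["tumor_volume_mm3"]), np.log(df["energy_wmin"])]))
        y = np.log(df["volume_cm3"] / df["vendor_volume_cm3"])
        ols = sm.OLS(y, X).fit()
        got = res["effect_size"].to_numpy()
        assert np.allclose(np.log(got), ols.params, atol=1e-5)

    def test_tip_to_edge_outcome_runs(self):
        rng = np.random.default_rng(9)
        df = self.make_cohort(rng, n_pat=50)
        res = fit_discrepancy_model(df, "tip_to_edge")
        assert set(res["outcome"]) == {"tip_to_edge"}
        assert len(res) == 5


class TestDistributionSummary:
    def test_large_normal_sample_moments(self, rng):
        s = distribution_summary(rng.normal(size=10000))
        assert abs(s.skewness) < 0.1
        assert s.kurtosis == pytest.approx(3.0, abs=0.2)
        assert s.ks_normal_p > 0.01

    def test_hand_computable_summary(self):
        s = distribution_summary(np.array([1.0, 2, 3, 4, 100]))
        assert s.median == 3.0
        assert s.iqr == 2.0
        assert s.skewness > 0
        assert s.mad == pytest.approx(np.mean(np.abs(np.array([1, 2, 3, 4, 100]) - 22.0)))

    def test_lognormal_is_skewed_and_heavy_tailed(self):
        hits = 0
        rng = np.random.default_rng(13)
        for _ in range(40):
            s = distribution_summary(rng.lognormal(0, 1, 200))
            hits += (s.skewness > 1) and (s.kurtosis > 3)
        assert hits / 40 >= 0.95

    def test_small_sample_skips_normality(self):
        s = distribution_summary(np.array([1.0, 2, 3, 4]))
        assert np.isnan(s.shapiro_p) and np.isnan(s.ks_normal_p)


class TestAdjustPvalues:
    def test_single_p_unchanged(self):
        assert adjust_pvalues([0.03])[0] == pytest.approx(0.03)

    def test_holm_hand_calculation(self):
        adj = adjust_pvalues([0.01, 0.02, 0.03])
        assert np.allclose(adj, [0.03, 0.04, 0.04])

    def test_all_ones_stay_one(self):
        assert np.all(adjust_pvalues([1.0, 1.0, 1.0]) == 1.0)

    def test_monotone_and_bounded(self, rng):
        p = rng.uniform(size=12)
        adj = adjust_pvalues(p)
        assert np.all(adj >= p) and np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5])


# ---------------------------------------------------------------------------
# property-based checks

from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12))
def test_holm_adjustment_properties(pvals):
    """Adjusted p-values are >= raw, <= 1, and monotone in the raw order."""
    p = np.asarray(pvals)
    adj = adjust_pvalues(p)
    assert np.all(adj >= p - 1e-15)
    assert np.all(adj <= 1.0)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)
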