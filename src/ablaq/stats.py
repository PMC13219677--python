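"""Cluster-aware cohort inference.

Patients often receive more than one ablation, so per-ablation observations
are not independent: every test here accounts for patient-level clustering.

* ``clustered_signed_rank`` — a clustered Wilcoxon signed-rank test in the
  Rosner–Glynn–Lee spirit: signed ranks are computed over all observations
  and the variance of their sum is estimated from the cluster-level sums,
  T = sum(s_i), Var(T) = sum_c (sum_{i in c} s_i)^2, Z = T / sqrt(Var).
  With singleton clusters this reduces exactly to the classical normal
  approximation (sum of squared ranks in the denominator, average-rank
  ties, no continuity correction).  Zero differences are dropped.  A
  confidence interval for the location shift is obtained by test inversion
  over a grid of shifts.
* ``clustered_correlation`` — Pearson (or Spearman) correlation with a
  patient-level (cluster) bootstrap for inference; resampling whole
  patients preserves within-patient dependence.
* ``fit_discrepancy_model`` — random-intercept linear mixed model of the
  log observed/vendor discrepancy on tissue contraction, follow-up time,
  log energy and log tumor volume, reported as exponentiated coefficients.
* ``distribution_summary`` — the robust/moment summary used for per-setting
  volume distributions, plus normality tests.
* ``adjust_pvalues`` — multiplicity adjustment (Holm by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ClusteredSample",
    "SignedRankResult",
    "CorrelationResult",
    "DistributionSummary",
    "clustered_signed_rank",
    "clustered_correlation",
    "fit_discrepancy_model",
    "distribution_summary",
    "adjust_pvalues",
]


@dataclass
class ClusteredSample:
    """Values (e.g. paired differences) with their cluster (patient) ids."""

    values: np.ndarray
    clusters: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.clusters = np.asarray(self.clusters)
        if self.values.shape != self.clusters.shape:
            raise ValueError("values and clusters must have equal length")


@dataclass
class SignedRankResult:
    statistic: float        # Z = T / sqrt(Var)
    p: float
    t_sum: float            # sum of signed ranks
    ci_low: float
    ci_high: float
    n: int                  # non-zero differences used
    n_clusters: int


@dataclass
class CorrelationResult:
    r: float
    p: float
    ci_low: float
    ci_high: float
    n: int
    n_clusters: int
    method: str


def _signed_rank_z(diffs: np.ndarray, cluster_idx: np.ndarray, n_clusters: int):
    """(Z, T) for non-zero diffs; average-rank ties, cluster-sum variance."""
    ranks = sps.rankdata(np.abs(diffs))
    s = np.sign(diffs) * ranks
    t = float(s.sum())
    sums = np.bincount(cluster_idx, weights=s, minlength=n_clusters)
    var = float((sums**2).sum())
    if var == 0:
        return 0.0, t
    return t / np.sqrt(var), t


def clustered_signed_rank(
    diffs: np.ndarray,
    clusters: np.ndarray,
    ci_level: float = 0.95,
    ci_grid: int = 201,
    compute_ci: bool = True,
) -> SignedRankResult:
    """Clustered Wilcoxon signed-rank test of median difference = 0.

    Zero differences are dropped before ranking (the classical convention);
    ties in |diff| receive average ranks.  The two-sided p-value uses the
    normal approximation Z = T / sqrt(sum of squared cluster sums).  The CI
    for the location shift inverts the test over a grid of candidate shifts.
    """
    diffs = np.asarray(diffs, dtype=float)
    clusters = np.asarray(clusters)
    if diffs.shape != clusters.shape:
        raise ValueError("diffs and clusters must have equal length")
    nz = diffs != 0
    d, c = diffs[nz], clusters[nz]
    if len(d) == 0:
        raise ValueError("all differences are zero")
    uniq, idx = np.unique(c, return_inverse=True)
    n_cl = len(uniq)
    if n_cl < 2:
        raise ValueError("clustered test requires at least 2 clusters")
    z, t = _signed_rank_z(d, idx, n_cl)
    p = float(2.0 * sps.norm.sf(abs(z)))

    ci_low = ci_high = np.nan
    if compute_ci:
        zcrit = sps.norm.ppf(0.5 + ci_level / 2.0)
        grid = np.linspace(float(d.min()), float(d.max()), ci_grid)
        accepted = []
        for shift in grid:
            ds = d - shift
            keep = ds != 0
            zs, _ = _signed_rank_z(ds[keep], idx[keep], n_cl)
            if abs(zs) <= zcrit:
                accepted.append(shift)
        if accepted:
            ci_low, ci_high = float(min(accepted)), float(max(accepted))
        else:
            ci_low = ci_high = float(np.median(d))
    return SignedRankResult(
        statistic=float(z), p=min(p, 1.0), t_sum=t,
        ci_low=ci_low, ci_high=ci_high,
        n=int(len(d)), n_clusters=n_cl,
    )


def clustered_correlation(
    x: np.ndarray,
    y: np.ndarray,
    clusters: np.ndarray,
    method: str = "pearson",
    n_boot: int = 2000,
    ci_level: float = 0.95,
    seed: int = 0,
) -> CorrelationResult:
    """Correlation with cluster-bootstrap inference.

    The point estimate is the plain correlation over all observations; the
    CI and p-value come from resampling whole clusters (patients) with
    replacement, B = ``n_boot``.  The p-value is the bootstrap CI-inversion
    form 2·min(P(r* <= 0), P(r* >= 0)).  ``method`` may be "pearson" or the
    rank-based "spearman".
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    clusters = np.asarray(clusters)
    if not (len(x) == len(y) == len(clusters)):
        raise ValueError("x, y and clusters must have equal length")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    if method == "spearman":
        xr, yr = sps.rankdata(x), sps.rankdata(y)
    elif method == "pearson":
        xr, yr = x, y
    else:
        raise ValueError(f"unknown method {method!r}")
    r = float(np.corrcoef(xr, yr)[0, 1])

    uniq, inv = np.unique(clusters, return_inverse=True)
    n_cl = len(uniq)
    rng = np.random.default_rng(seed)
    # cluster resampling keeps whole patients together; for Pearson the
    # sufficient statistics are additive over clusters, so the bootstrap is
    # fully vectorised
    if method == "pearson":
        stats = np.zeros((n_cl, 6))
        np.add.at(stats, inv, np.stack(
            [np.ones_like(x), x, y, x * x, y * y, x * y], axis=1))
        pick = rng.integers(0, n_cl, size=(n_boot, n_cl))
        S = stats[pick].sum(axis=1)  # (B, 6)
        n_, sx, sy, sxx, syy, sxy = S.T
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = sxy - sx * sy / n_
            vx = sxx - sx**2 / n_
            vy = syy - sy**2 / n_
            rb = cov / np.sqrt(vx * vy)
    else:
        idx_by_cl = [np.nonzero(inv == i)[0] for i in range(n_cl)]
        rb = np.empty(n_boot)
        for b in range(n_boot):
            pick = rng.integers(0, n_cl, size=n_cl)
            ii = np.concatenate([idx_by_cl[i] for i in pick])
            xs, ys = sps.rankdata(x[ii]), sps.rankdata(y[ii])
            if np.std(xs) == 0 or np.std(ys) == 0:
                rb[b] = np.nan
            else:
                rb[b] = np.corrcoef(xs, ys)[0, 1]
    rb = rb[np.isfinite(rb)]
    if len(rb) == 0:
        raise ValueError("all bootstrap replicates degenerate")
    alpha = 1.0 - ci_level
    ci_low, ci_high = np.quantile(rb, [alpha / 2, 1 - alpha / 2])
    frac_le = (np.sum(rb <= 0) + 1) / (len(rb) + 1)
    frac_ge = (np.sum(rb >= 0) + 1) / (len(rb) + 1)
    p = float(min(1.0, 2.0 * min(frac_le, frac_ge)))
    return CorrelationResult(
        r=r, p=p, ci_low=float(ci_low), ci_high=float(ci_high),
        n=len(x), n_clusters=n_cl, method=method,
    )


_MODEL_TERMS = [
    ("Intercept", "Intercept"),
    ("followup_days", "Time to follow up (per 1 day)"),
    ("contraction_mm", "Tissue contraction (per 1 mm)"),
    ("log_tumor_volume", "log(tumor volume)"),
    ("log_energy", "log(ablation energy)"),
]


def fit_discrepancy_model(cohort: pd.DataFrame, outcome: str = "volume") -> pd.DataFrame:
    """Random-intercept mixed model of the log observed/vendor discrepancy.

    outcome: "volume" (uses volume_cm3 / vendor_volume_cm3) or
    "tip_to_edge" (tip_to_edge_mm / vendor_tip_to_edge_mm).  Fixed effects:
    tissue contraction (mm), time to follow-up (days), log tumor volume and
    log ablation energy; random effect: patient intercept.  Coefficients
    are reported exponentiated (with 95% CIs), so the intercept row is the
    multiplicative residual discrepancy after covariate adjustment.  A
    singular mixed fit falls back to OLS with cluster-robust errors.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    cols = {
        "volume": ("volume_cm3", "vendor_volume_cm3"),
        "tip_to_edge": ("tip_to_edge_mm", "vendor_tip_to_edge_mm"),
    }
    try:
        obs_col, ven_col = cols[outcome]
    except KeyError:
        raise ValueError(f"unknown outcome {outcome!r}") from None
    need = [obs_col, ven_col, "contraction_mm", "followup_days",
            "tumor_volume_mm3", "energy_wmin", "patient_id"]
    df = cohort[need].dropna().copy()
    if len(df) < 8:
        raise ValueError("too few complete rows for the discrepancy model")
    if (df[[obs_col, ven_col, "tumor_volume_mm3", "energy_wmin"]] <= 0).any().any():
        raise ValueError("log transforms require positive observed/vendor/covariates")
    df["discrepancy"] = np.log(df[obs_col] / df[ven_col])
    df["log_tumor_volume"] = np.log(df["tumor_volume_mm3"])
    df["log_energy"] = np.log(df["energy_wmin"])

    formula = "discrepancy ~ followup_days + contraction_mm + log_tumor_volume + log_energy"
    fallback = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm(formula, df, groups=df["patient_id"]).fit(reml=True)
        if not np.all(np.isfinite(fit.bse_fe)):
            raise np.linalg.LinAlgError("non-finite standard errors")
        params = fit.fe_params
        conf = fit.conf_int().loc[params.index]
        pvals = fit.pvalues.loc[params.index]
    except (np.linalg.LinAlgError, ValueError):
        fallback = True
    if fallback:
        warnings.warn("singular mixed-model fit; falling back to cluster-robust OLS")
        X = sm.add_constant(df[["followup_days", "contraction_mm",
                                "log_tumor_volume", "log_energy"]])
        ols = sm.OLS(df["discrepancy"], X).fit(
            cov_type="cluster", cov_kwds={"groups": df["patient_id"]})
        params = ols.params.rename(index={"const": "Intercept"})
        conf = ols.conf_int().rename(index={"const": "Intercept"})
        pvals = ols.pvalues.rename(index={"const": "Intercept"})

    rows = []
    for term, label in _MODEL_TERMS:
        rows.append({
            "outcome": outcome,
            "term": label,
            "effect_size": float(np.exp(params[term])),
            "ci_low": float(np.exp(conf.loc[term, 0])),
            "ci_high": float(np.exp(conf.loc[term, 1])),
            "p": float(pvals[term]),
            "estimator": "ols_cluster_robust" if fallback else "mixedlm",
        })
    return pd.DataFrame(rows)


@dataclass
class DistributionSummary:
    """Location/spread/shape summary of one subset's values.

    Kurtosis is in Pearson form (a normal distribution has kurtosis 3);
    skewness is the Fisher–Pearson g1.  ``mad`` is the mean absolute
    deviation about the mean.  Normality p-values are NaN when n < 8.
    """

    n: int
    median: float
    iqr: float
    mad: float
    skewness: float
    kurtosis: float
    ks_normal_p: float
    shapiro_p: float


def distribution_summary(values: np.ndarray) -> DistributionSummary:
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 3:
        raise ValueError("need at least 3 values for a distribution summary")
    q1, q3 = np.percentile(v, [25, 75])
    mad = float(np.mean(np.abs(v - v.mean())))
    skew = float(sps.skew(v))
    kurt = float(sps.kurtosis(v, fisher=False))
    if len(v) >= 8 and np.std(v) > 0:
        ks_p = float(sps.kstest((v - v.mean()) / v.std(ddof=1), "norm").pvalue)
        shapiro_p = float(sps.shapiro(v).pvalue)
    else:
        ks_p = shapiro_p = np.nan
    return DistributionSummary(
        n=len(v), median=float(np.median(v)), iqr=float(q3 - q1),
        mad=mad, skewness=skew, kurtosis=kurt,
        ks_normal_p=ks_p, shapiro_p=shapiro_p,
    )


def adjust_pvalues(pvals, method: str = "holm") -> np.ndarray:
    """Multiplicity adjustment; monotone, >= raw, <= 1."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method=method)[1]
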