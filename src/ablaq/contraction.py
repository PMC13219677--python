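"""Tissue-contraction quantification from paired anatomical landmarks.

Post-ablation involution and cicatrization pull the surrounding parenchyma
inward over the weeks between the pre-procedure and follow-up CT.  Rather
than registering the two scans, contraction is quantified from a handful
(3–10) of anatomical landmarks — e.g. vessel bifurcations — identified in
both scans: all pairwise Euclidean distances are computed in each scan and
contraction is the mean decrease in distance, in mm.  Being distance-based,
the statistic is invariant to any rigid motion between the scans, which is
exactly why no registration is needed.

Sign convention: positive = shrinkage (distances decreased), negative =
expansion.  Uniformly scaling the post scan by a factor s about any centre
gives contraction (1 - s) × mean pre-distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import mannwhitneyu, wilcoxon

__all__ = [
    "LandmarkSet",
    "ContractionResult",
    "pairwise_distances",
    "contraction_statistic",
    "contraction_correlates",
]

logger = logging.getLogger(__name__)


@dataclass
class LandmarkSet:
    """Labeled world points (mm) for one scan of one ablation."""

    labels: list
    points: np.ndarray
    role: str = "pre"  # pre | post
    ablation_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.labels = [str(l) for l in self.labels]
        if len(self.labels) != len(self.points):
            raise ValueError("labels and points length mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate landmark labels")
        n = len(self.labels)
        if not (3 <= n <= 10):
            logger.warning(
                "landmark set has %d points; the protocol uses 3-10", n
            )

    def sorted_points(self) -> np.ndarray:
        order = np.argsort(np.asarray(self.labels, dtype=object))
        return self.points[order]


@dataclass
class ContractionResult:
    mean_contraction_mm: float
    pair_changes_mm: np.ndarray          # d_pre - d_post per landmark pair
    p_value: float                       # two-sample Mann-Whitney on distances
    p_value_paired: float                # paired Wilcoxon sensitivity variant
    n_landmarks: int
    n_pairs: int


def pairwise_distances(points: np.ndarray) -> np.ndarray:
    """Condensed vector of all unordered pairwise Euclidean distances."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 2:
        raise ValueError("need at least 2 points for pairwise distances")
    return pdist(pts)


def contraction_statistic(pre: LandmarkSet, post: LandmarkSet) -> ContractionResult:
    """Mean pairwise distance decrease between pre and post landmark sets.

    Landmarks are matched by label (pair order is label-sorted and identical
    in both scans).  Significance is assessed with a two-sample Mann-Whitney
    test comparing the pre- and post-distance samples; a paired Wilcoxon on
    the per-pair differences is also reported as a sensitivity variant.
    """
    if set(pre.labels) != set(post.labels):
        extra_pre = sorted(set(pre.labels) - set(post.labels))
        extra_post = sorted(set(post.labels) - set(pre.labels))
        raise ValueError(
            f"landmark label mismatch: only in pre {extra_pre}, only in post {extra_post}"
        )
    d_pre = pairwise_distances(pre.sorted_points())
    d_post = pairwise_distances(post.sorted_points())
    changes = d_pre - d_post
    if np.allclose(d_pre, d_post):
        p_mw, p_paired = 1.0, 1.0
    else:
        p_mw = float(mannwhitneyu(d_pre, d_post, alternative="two-sided").pvalue)
        try:
            p_paired = float(wilcoxon(changes).pvalue)
        except ValueError:  # all differences zero
            p_paired = 1.0
    return ContractionResult(
        mean_contraction_mm=float(changes.mean()),
        pair_changes_mm=changes,
        p_value=p_mw,
        p_value_paired=p_paired,
        n_landmarks=len(pre.labels),
        n_pairs=len(changes),
    )


def contraction_correlates(
    table,
    covariates=("volume_cm3", "power_w", "duration_min", "followup_days"),
    contraction_col: str = "contraction_mm",
    cluster_col: str = "patient_id",
    n_boot: int = 2000,
    seed: int = 0,
):
    """Cluster-aware correlations of contraction against cohort covariates.

    Returns a DataFrame with one row per covariate (r, p, n).  Covariates or
    contraction with zero variance yield NaN r and p (reported, not raised).
    Requires >= 3 complete rows per covariate.
    """
    import pandas as pd

    from .stats import clustered_correlation

    rows = []
    for cov in covariates:
        sub = table[[contraction_col, cov, cluster_col]].dropna()
        if len(sub) < 3:
            raise ValueError(f"fewer than 3 complete rows for covariate {cov!r}")
        x = sub[contraction_col].to_numpy(float)
        y = sub[cov].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append({"covariate": cov, "r": np.nan, "p": np.nan, "n": len(sub)})
            continue
        res = clustered_correlation(
            x, y, sub[cluster_col].to_numpy(), n_boot=n_boot, seed=seed
        )
        rows.append({"covariate": cov, "r": res.r, "p": res.p, "n": len(sub)})
    return pd.DataFrame(rows)
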