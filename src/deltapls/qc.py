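"""Scan-level quality control and multivariate outlier screening.

Two screens are provided.  The intensity screen compares a scan's in-mask
mean, variance and (adjusted Fisher-Pearson) skew to the control
distribution of the same metrics, flagging Bonferroni-significant
Z-scores.  The multivariate screen — because covariance-based analyses are
sensitive to single extreme maps — projects scans onto the principal
components that retain 90% of control-set variance, standardizes the
scores robustly (median/MAD), and flags scans whose squared robust
distance exceeds a Bonferroni-adjusted chi-square tail cutoff.  Flagged
scans are excluded from all downstream fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .io import ParameterMap

METRICS = ("mean", "variance", "skew")


@dataclass
class QCStats:
    """Intensity-distribution QC result for one scan."""

    subject_id: str
    metrics: dict[str, float]
    z: dict[str, float]
    flagged: bool


def _intensity_metrics(values: np.ndarray) -> np.ndarray:
    return np.array([
        float(np.mean(values)),
        float(np.var(values, ddof=1)),
        float(stats.skew(values, bias=False)),
    ])


def intensity_qc(
    image: ParameterMap,
    controls: list[ParameterMap],
    alpha: float = 0.05,
    n_tests: int = 3,
) -> QCStats:
    """Flag a scan whose intensity-distribution metrics are control outliers.

    Each metric's Z-score is referred to the normal distribution; the scan
    is flagged if any two-sided p falls below the Bonferroni level
    ``alpha / n_tests``.
    """
    if len(controls) < 3:
        raise ValueError("intensity QC needs at least 3 control scans")
    stat = _intensity_metrics(image.values)
    ctrl = np.vstack([_intensity_metrics(c.values) for c in controls])
    mu = ctrl.mean(axis=0)
    sd = ctrl.std(axis=0, ddof=1)
    for name, s in zip(METRICS, sd):
        if s == 0:
            raise ValueError(f"zero control variability for metric {name!r}")
    z = (stat - mu) / sd
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    flagged = bool((pvals < alpha / n_tests).any())
    return QCStats(
        subject_id=image.subject_id,
        metrics=dict(zip(METRICS, stat)),
        z=dict(zip(METRICS, z)),
        flagged=flagged,
    )


class MultivariateOutlierDetector(BaseEstimator):
    """PCA + robust-Mahalanobis outlier screen for voxel maps.

    ``fit`` learns the principal subspace retaining ``var_explained`` of
    the reference (control) set's variance; ``predict`` returns boolean
    flags for scans whose median/MAD-standardized component scores give a
    squared robust distance with chi-square upper-tail probability below
    ``alpha / n_scans`` (Bonferroni over the scans tested).
    """

    def __init__(self, var_explained: float = 0.9, alpha: float = 0.05):
        self.var_explained = var_explained
        self.alpha = alpha

    def fit(self, X: np.ndarray, y=None) -> "MultivariateOutlierDetector":
        X = np.asarray(X, float)
        if X.shape[0] < 5:
            raise ValueError("need at least 5 reference scans")
        total_var = float(np.var(X - X.mean(axis=0), ddof=0))
        if total_var <= 1e-30:
            # perfectly homogeneous reference set: no directions to screen
            self.pca_ = None
            self.median_ = np.zeros(0)
            self.mad_ = np.zeros(0)
            return self
        n_comp = min(X.shape[0] - 1, X.shape[1])
        pca = PCA(n_components=n_comp).fit(X)
        cum = np.cumsum(pca.explained_variance_ratio_)
        k = int(np.searchsorted(cum, self.var_explained) + 1)
        k = min(k, n_comp)
        self.pca_ = PCA(n_components=k).fit(X)
        scores = self.pca_.transform(X)
        self.median_ = np.median(scores, axis=0)
        self.mad_ = 1.4826 * np.median(
            np.abs(scores - self.median_), axis=0
        )
        return self

    def distances(self, X: np.ndarray) -> np.ndarray:
        """Squared robust Mahalanobis distances in the retained subspace."""
        if self.pca_ is None:
            return np.zeros(len(X))
        scores = self.pca_.transform(np.asarray(X, float))
        diff = scores - self.median_
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(
                self.mad_ > 0, diff / np.where(self.mad_ > 0, self.mad_, 1.0),
                np.where(diff == 0, 0.0, np.inf),
            )
        return (z ** 2).sum(axis=1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        if X.shape[0] < 5:
            raise ValueError("need at least 5 scans to screen")
        if self.pca_ is None:
            return np.zeros(X.shape[0], dtype=bool)
        d2 = self.distances(X)
        df = self.pca_.n_components_
        pvals = stats.chi2.sf(d2, df=df)
        pvals = np.where(np.isinf(d2), 0.0, pvals)
        return pvals < self.alpha / X.shape[0]


def multivariate_outliers(maps: np.ndarray, alpha: float = 0.05,
                          var_explained: float = 0.9) -> np.ndarray:
    """Boolean outlier flags for a subjects-by-voxels matrix of maps.

    The screen is fit and applied on the same matrix (self-reference); use
    the estimator directly to fit on controls and screen other scans.
    """
    maps = np.asarray(maps, float)
    det = MultivariateOutlierDetector(var_explained=var_explained,
                                      alpha=alpha).fit(maps)
    return det.predict(maps)


def qc_report(stats_list: list[QCStats]) -> pd.DataFrame:
    """Tabulate intensity-QC results (one row per scan)."""
    rows = []
    for s in stats_list:
        row = {"subject_id": s.subject_id, "flagged": s.flagged}
        row.update({f"metric_{k}": v for k, v in s.metrics.items()})
        row.update({f"z_{k}": v for k, v in s.z.items()})
        rows.append(row)
    return pd.DataFrame(rows)
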