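"""Condition-by-voxel summary matrices and uncentered task PLS.

Two 3 x V summary matrices are built per modality from the athletes'
difference maps: the per-session mean Δ maps (MEAN analysis, the main
effect of concussion) and the per-session point-biserial correlations of Δ
with sex (SEXCORR analysis, the sex-specific effect).  Missing sessions
are simply omitted from the relevant cell.  Each matrix is decomposed by a
singular value decomposition WITHOUT any row or column centering — the
task-PLS convention for condition summaries — and the leading singular
triplet is reported as the paired voxel salience / session salience
pattern, with the fraction of total squared singular value as the percent
covariance explained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .io import SESSIONS

MEAN = "MEAN"
SEXCORR = "SEXCORR"


@dataclass
class SummaryMatrix:
    """A 3 (sessions) x V (voxels) condition summary for one analysis."""

    kind: str                      # MEAN or SEXCORR
    values: np.ndarray             # (3, V)
    n_used: np.ndarray             # athletes contributing per session
    sessions: tuple[str, ...] = SESSIONS
    n_zero_variance: int = 0       # SEXCORR voxels set to 0 by convention


@dataclass
class PLSComponent:
    """Leading singular triplet of an uncentered condition summary."""

    voxel_salience: np.ndarray     # unit vector, length V
    session_salience: np.ndarray   # unit vector, length 3
    singular_values: np.ndarray    # all singular values, descending
    pct_covariance: float          # 100 * s1^2 / sum(s^2)


def session_mean_maps(deltas: np.ndarray) -> SummaryMatrix:
    """Per-session mean difference maps, missing athletes omitted.

    ``deltas`` is (athletes, sessions, voxels) with NaN rows for missing
    sessions.
    """
    deltas = np.asarray(deltas, float)
    available = ~np.isnan(deltas[:, :, 0])
    n_used = available.sum(axis=0)
    if np.any(n_used < 2):
        raise ValueError(
            f"each session needs >=2 athletes with data, got {n_used}"
        )
    with np.errstate(invalid="ignore"):
        values = np.nanmean(deltas, axis=0)
    return SummaryMatrix(kind=MEAN, values=values, n_used=n_used)


def session_sex_correlation_maps(
    deltas: np.ndarray, sex: np.ndarray
) -> SummaryMatrix:
    """Per-session voxelwise correlation of Δ with sex (0=male, 1=female).

    The point-biserial (Pearson) correlation is computed across the
    athletes with data at that session.  Voxels where Δ has zero variance
    get correlation 0 by convention (counted in ``n_zero_variance``).
    """
    deltas = np.asarray(deltas, float)
    sex = np.asarray(sex, float)
    n_sessions, V = deltas.shape[1], deltas.shape[2]
    values = np.zeros((n_sessions, V))
    n_used = np.zeros(n_sessions, dtype=int)
    n_zero = 0
    for s in range(n_sessions):
        avail = ~np.isnan(deltas[:, s, 0])
        xs = sex[avail]
        if (xs == 0).sum() < 2 or (xs == 1).sum() < 2:
            raise ValueError(
                f"session index {s}: need >=2 athletes of each sex"
            )
        Y = deltas[avail, s, :]
        xc = xs - xs.mean()
        Yc = Y - Y.mean(axis=0)
        num = xc @ Yc
        sy = np.sqrt((Yc ** 2).sum(axis=0))
        sx = np.sqrt((xc ** 2).sum())
        degenerate = sy == 0
        n_zero += int(degenerate.sum())
        denom = np.where(degenerate, 1.0, sx * sy)
        values[s] = np.where(degenerate, 0.0, num / denom)
        n_used[s] = int(avail.sum())
    return SummaryMatrix(kind=SEXCORR, values=values, n_used=n_used,
                         n_zero_variance=n_zero)


class UncenteredPLS(BaseEstimator):
    """Task PLS of a condition-by-voxel summary matrix via uncentered SVD.

    No row or column centering is applied before the decomposition (grand-
    mean removal is deliberately NOT performed), so the first component
    captures the dominant shared pattern across conditions, including any
    common offset.  Sign convention: within each component, the session
    salience element of largest magnitude is made positive, applied jointly
    to the session and voxel sides.

    Attributes (after ``fit``)
    --------------------------
    session_saliences_ : (n_conditions, n_components) columns are unit vectors
    voxel_saliences_ : (n_components, V) rows are unit vectors
    singular_values_ : (n_components,) descending
    pct_covariance_ : (n_components,) 100 * s_i^2 / sum(s^2)
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X: np.ndarray, y=None) -> "UncenteredPLS":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D condition-by-voxel matrix")
        if not np.all(np.isfinite(X)):
            raise ValueError("summary matrix contains non-finite values")
        if not np.any(X):
            raise ValueError("summary matrix is identically zero")
        u, s, vt = np.linalg.svd(X, full_matrices=False)
        k = s.size if self.n_components is None else min(self.n_components, s.size)
        u, s, vt = u[:, :k], s[:k], vt[:k]
        for i in range(k):
            j = int(np.argmax(np.abs(u[:, i])))
            if u[j, i] < 0:
                u[:, i] = -u[:, i]
                vt[i] = -vt[i]
        total = float((s ** 2).sum())
        self.session_saliences_ = u
        self.voxel_saliences_ = vt
        self.singular_values_ = s
        self.pct_covariance_ = 100.0 * s ** 2 / total
        return self

    def first_component(self) -> PLSComponent:
        return PLSComponent(
            voxel_salience=self.voxel_saliences_[0],
            session_salience=self.session_saliences_[:, 0],
            singular_values=self.singular_values_,
            pct_covariance=float(self.pct_covariance_[0]),
        )


def uncentered_pls(summary: SummaryMatrix | np.ndarray) -> PLSComponent:
    """First uncentered-PLS component of a summary matrix."""
    values = summary.values if isinstance(summary, SummaryMatrix) else summary
    return UncenteredPLS().fit(values).first_component()


def build_summary(
    deltas: np.ndarray, sex: np.ndarray | None, analysis: str
) -> SummaryMatrix:
    """Dispatch to the MEAN or SEXCORR summary for a delta tensor."""
    if analysis == MEAN:
        return session_mean_maps(deltas)
    if analysis == SEXCORR:
        if sex is None:
            raise ValueError("SEXCORR analysis requires the sex vector")
        return session_sex_correlation_maps(deltas, sex)
    raise ValueError(f"unknown analysis {analysis!r}")
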