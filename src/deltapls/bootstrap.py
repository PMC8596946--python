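"""Repeated-measures bootstrap inference for PLS saliences and ROI effects.

The resampling unit is a concussed athlete together with all of their
session difference maps (the ACU/RTP/YR1 triplet is never split across
athletes).  Within every bootstrap replicate, the partially missing
athlete-by-(session,voxel) matrix is completed by SOFT-IMPUTE at a fixed,
cross-validation-chosen soft threshold before the condition summary and
the uncentered PLS are rebuilt; the candidate component is sign-aligned to
the reference fit before accumulation.  Standardized effect sizes are
bootstrap ratios (BSR = bootstrap mean / bootstrap SE), referred to the
standard normal for p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import SESSIONS
from .impute import ImputationModel, soft_impute
from .pls import MEAN, SEXCORR, PLSComponent, build_summary, uncentered_pls
from .clinical import fdr_adjust


@dataclass
class BootstrapResult:
    """Bootstrap summary of one PLS analysis."""

    analysis: str
    component: PLSComponent            # point estimate (missing omitted)
    voxel_bsr: np.ndarray
    session_bsr: np.ndarray
    voxel_p: np.ndarray
    session_p: np.ndarray
    pct_cov_point: float
    pct_cov_ci: tuple[float, float]
    boot_mean_voxel: np.ndarray
    boot_mean_session: np.ndarray
    n_boot: int
    seed: int | None
    n_degenerate: int
    n_redrawn: int


def align_component(
    reference: PLSComponent, candidate: PLSComponent
) -> PLSComponent:
    """Flip the candidate's joint sign to agree with the reference.

    The sign is that of the inner product of the voxel saliences (+1 on an
    exact zero), applied to both the voxel and session sides so the
    component stays a valid singular pair.
    """
    dot = float(reference.voxel_salience @ candidate.voxel_salience)
    sign = 1.0 if dot >= 0 else -1.0
    if sign > 0:
        return candidate
    return PLSComponent(
        voxel_salience=-candidate.voxel_salience,
        session_salience=-candidate.session_salience,
        singular_values=candidate.singular_values,
        pct_covariance=candidate.pct_covariance,
    )


def _bsr(total: np.ndarray, total_sq: np.ndarray, n: int):
    """Bootstrap mean, SE, BSR and normal p from accumulated moments.

    Zero bootstrap SE yields a signed-infinity BSR sentinel with p = 0.
    """
    mean = total / n
    var = np.maximum(total_sq / n - mean ** 2, 0.0) * n / (n - 1)
    se = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        bsr = np.where(se > 0, mean / np.where(se > 0, se, 1.0),
                       np.sign(mean) * np.inf)
    bsr = np.where((se == 0) & (mean == 0), 0.0, bsr)
    p = np.where(np.isinf(bsr), 0.0, 2.0 * stats.norm.sf(np.abs(bsr)))
    n_degenerate = int(np.sum(se == 0))
    return mean, se, bsr, p, n_degenerate


def _impute_resample(X: np.ndarray, Z0: np.ndarray, idx: np.ndarray,
                     imputation: ImputationModel,
                     impute_max_iter: int) -> np.ndarray:
    """Complete a resampled matrix, warm-started from the full-data fit Z0.

    A resample may leave an entire column block unobserved (every drawn
    athlete missing the same session); those columns carry no information
    in the replicate and are taken from the full-data completion before
    the SVT sweeps.
    """
    Xb = X[idx].copy()
    if not np.isnan(Xb).any():
        return Xb
    dead = np.isnan(Xb).all(axis=0)
    if dead.any():
        Xb[:, dead] = Z0[idx][:, dead]
    if not np.isnan(Xb).any():
        return Xb
    with warnings.catch_warnings():
        # the sweep cap is a per-replicate computational budget; hitting
        # it is expected and not worth a warning per replicate
        warnings.filterwarnings("ignore", message="soft-impute did not")
        return soft_impute(Xb, imputation.chosen_lambda, tol=imputation.tol,
                           max_iter=impute_max_iter,
                           max_rank=imputation.max_rank, init=Z0[idx])


def _valid_resample(idx: np.ndarray, sex: np.ndarray | None,
                    analysis: str) -> bool:
    if np.unique(idx).size < 2:
        return False
    if analysis == SEXCORR:
        s = sex[idx]
        if (s == 0).sum() < 2 or (s == 1).sum() < 2:
            return False
    return True


def bootstrap_pls(
    deltas: np.ndarray,
    sex: np.ndarray | None,
    analysis: str = MEAN,
    n_boot: int = 1000,
    seed: int | None = None,
    imputation: ImputationModel | None = None,
    impute_max_iter: int = 100,
) -> BootstrapResult:
    """Repeated-measures bootstrap of the first uncentered-PLS component.

    ``deltas`` is (athletes, sessions, voxels) with NaN marking missing
    sessions; the point estimate is fit with the missing entries omitted
    from the summary, while each bootstrap replicate imputes its resampled
    matrix with SOFT-IMPUTE at ``imputation.chosen_lambda`` (required when
    any session is missing).  Replicates that degenerate (a single distinct
    athlete; for the sex analysis, fewer than two athletes of either sex)
    are redrawn and counted.
    """
    deltas = np.asarray(deltas, float)
    n, n_sessions, V = deltas.shape
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable bootstrap ratios",
                      stacklevel=2)
    summary = build_summary(deltas, sex, analysis)
    reference = uncentered_pls(summary)

    X = deltas.reshape(n, n_sessions * V)
    has_missing = bool(np.isnan(X).any())
    if has_missing and imputation is None:
        raise ValueError(
            "missing sessions present: supply an ImputationModel "
            "(e.g. from select_lambda_cv)"
        )
    if has_missing:
        Z0 = soft_impute(X, imputation.chosen_lambda, tol=imputation.tol,
                         max_iter=500, max_rank=imputation.max_rank)
    else:
        Z0 = X

    rng = np.random.default_rng(seed)
    vox_sum = np.zeros(V)
    vox_sq = np.zeros(V)
    ses_sum = np.zeros(n_sessions)
    ses_sq = np.zeros(n_sessions)
    pcts = np.empty(n_boot)
    n_redrawn = 0

    for b in range(n_boot):
        for _ in range(1000):
            idx = rng.integers(0, n, size=n)
            if _valid_resample(idx, sex, analysis):
                break
            n_redrawn += 1
        Zb = _impute_resample(X, Z0, idx, imputation, impute_max_iter) \
            if has_missing else X[idx]
        db = Zb.reshape(-1, n_sessions, V)
        comp = uncentered_pls(
            build_summary(db, None if sex is None else sex[idx], analysis)
        )
        comp = align_component(reference, comp)
        s1 = comp.singular_values[0]
        vox_sum += s1 * comp.voxel_salience
        vox_sq += (s1 * comp.voxel_salience) ** 2
        ses_sum += s1 * comp.session_salience
        ses_sq += (s1 * comp.session_salience) ** 2
        pcts[b] = comp.pct_covariance

    _, _, voxel_bsr, voxel_p, deg_v = _bsr(vox_sum, vox_sq, n_boot)
    _, _, session_bsr, session_p, deg_s = _bsr(ses_sum, ses_sq, n_boot)
    lo, hi = np.percentile(pcts, [2.5, 97.5])
    return BootstrapResult(
        analysis=analysis,
        component=reference,
        voxel_bsr=voxel_bsr,
        session_bsr=session_bsr,
        voxel_p=voxel_p,
        session_p=session_p,
        pct_cov_point=reference.pct_covariance,
        pct_cov_ci=(float(lo), float(hi)),
        boot_mean_voxel=vox_sum / n_boot,
        boot_mean_session=ses_sum / n_boot,
        n_boot=n_boot,
        seed=seed,
        n_degenerate=deg_v + deg_s,
        n_redrawn=n_redrawn,
    )


@dataclass
class ROIStats:
    """Per-group/session cluster-averaged effect statistics.

    ``table`` mirrors the study's reporting layout: one row per group
    (all/male/female) and session with the cluster-mean Δ, bootstrapped
    95% CI, BSR, normal p and a BH-FDR significance flag across the three
    sessions of each group block.  ``contrast`` holds the sex-collapsed
    female-minus-male difference pooled over the requested sessions.
    """

    table: pd.DataFrame
    contrast: dict = field(default_factory=dict)


def _group_session_means(block: np.ndarray) -> np.ndarray:
    """Mean over athletes and cluster voxels per session, NaN-omitted."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(block, axis=(0, 2))


def roi_statistics(
    deltas: np.ndarray,
    sex: np.ndarray,
    cluster_mask: np.ndarray,
    groups: tuple[str, ...] = ("all",),
    n_boot: int = 1000,
    seed: int | None = None,
    imputation: ImputationModel | None = None,
    contrast_sessions: tuple[str, ...] | None = None,
    q: float = 0.05,
    impute_max_iter: int = 100,
    cv_repeats: int = 200,
) -> ROIStats:
    """Bootstrap effect statistics averaged over a significant-cluster mask.

    The statistic per group and session is the mean Δ over the group's
    athletes and the cluster voxels.  Δ is first averaged over the cluster
    voxels, giving the athletes-by-sessions matrix of ROI values; missing
    sessions leave holes in that matrix and are completed by SOFT-IMPUTE
    within every bootstrap replicate.  The soft threshold is
    cross-validated on the ROI matrix itself (``cv_repeats`` random 5%
    holdouts) unless an ``imputation`` model for that matrix is supplied —
    on a subjects-by-sessions matrix, held-out entries are exactly
    missing-session cells, so the selection is matched to the prediction
    task.  Bootstrapping resamples athletes within the group (sessions
    kept intact).  When ``groups`` contains both sexes, the female-minus-
    male contrast pooled over ``contrast_sessions`` (default: all three)
    is also bootstrapped, pairing the two sexes' independent resamples.
    """
    cluster_mask = np.asarray(cluster_mask, bool)
    if not cluster_mask.any():
        raise ValueError("cluster mask is empty")
    sub = np.asarray(deltas, float)[:, :, cluster_mask]
    n, n_sessions, _ = sub.shape
    sex = np.asarray(sex)
    rng = np.random.default_rng(seed)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        R = np.nanmean(sub, axis=2)          # athletes x sessions ROI means
    has_missing = bool(np.isnan(R).any())
    if has_missing:
        if imputation is None:
            from .impute import select_lambda_cv
            imputation = select_lambda_cv(
                R, n_iter=cv_repeats, holdout_frac=0.05,
                seed=int(rng.integers(2 ** 31 - 1)),
            )
        Z0 = soft_impute(R, imputation.chosen_lambda, tol=imputation.tol,
                         max_iter=500, max_rank=imputation.max_rank)
    else:
        Z0 = R

    def _complete(idx: np.ndarray) -> np.ndarray:
        if not has_missing:
            return R[idx]
        return _impute_resample(R, Z0, idx, imputation, impute_max_iter)

    members = {
        "all": np.arange(n),
        "male": np.flatnonzero(sex == 0),
        "female": np.flatnonzero(sex == 1),
    }
    rows = []
    boot_session_means: dict[str, np.ndarray] = {}
    for group in groups:
        idx = members[group]
        if idx.size == 0:
            raise ValueError(f"group {group!r} has no athletes")
        point = _group_session_means(sub[idx])
        boots = np.empty((n_boot, n_sessions))
        for b in range(n_boot):
            draw = idx[rng.integers(0, idx.size, size=idx.size)]
            while np.unique(draw).size < 2:
                draw = idx[rng.integers(0, idx.size, size=idx.size)]
            boots[b] = _complete(draw).mean(axis=0)
        boot_session_means[group] = boots
        mean_b = boots.mean(axis=0)
        se_b = boots.std(axis=0, ddof=1)
        # recentred percentile interval: the replicate statistics inherit
        # the imputation's shrinkage toward zero, which the omission-based
        # point estimate does not share; anchoring the percentile spread
        # at the point estimate removes that systematic shift
        q_lo, q_hi = np.percentile(boots, [2.5, 97.5], axis=0)
        lo = point + (q_lo - mean_b)
        hi = point + (q_hi - mean_b)
        with np.errstate(divide="ignore", invalid="ignore"):
            bsr = np.where(se_b > 0, mean_b / np.where(se_b > 0, se_b, 1.0),
                           np.sign(mean_b) * np.inf)
        pvals = np.where(np.isinf(bsr), 0.0, 2.0 * stats.norm.sf(np.abs(bsr)))
        flags = fdr_adjust(np.clip(pvals, np.finfo(float).tiny, 1.0), q=q)
        for s_i, session in enumerate(SESSIONS[:n_sessions]):
            rows.append({
                "group": group, "session": session,
                "mean": float(point[s_i]),
                "ci_low": float(lo[s_i]), "ci_high": float(hi[s_i]),
                "bsr": float(bsr[s_i]), "p": float(pvals[s_i]),
                "fdr_significant": bool(flags[s_i]),
            })

    result = ROIStats(table=pd.DataFrame(rows))

    if "male" in groups and "female" in groups:
        if contrast_sessions is None:
            contrast_sessions = SESSIONS[:n_sessions]
        s_idx = [SESSIONS.index(s) for s in contrast_sessions]
        f_idx, m_idx = members["female"], members["male"]
        point = (
            _group_session_means(sub[f_idx])[s_idx].mean()
            - _group_session_means(sub[m_idx])[s_idx].mean()
        )
        # the two sexes were resampled independently above, so their
        # replicate-wise difference is the contrast's bootstrap draw
        boots = (boot_session_means["female"][:, s_idx].mean(axis=1)
                 - boot_session_means["male"][:, s_idx].mean(axis=1))
        se_b = float(boots.std(ddof=1))
        bsr = float(boots.mean() / se_b) if se_b > 0 else float(
            np.sign(boots.mean()) * np.inf
        )
        q_lo, q_hi = np.percentile(boots, [2.5, 97.5])
        lo = point + (q_lo - boots.mean())
        hi = point + (q_hi - boots.mean())
        result.contrast = {
            "mean": float(point), "ci_low": float(lo), "ci_high": float(hi),
            "bsr": bsr,
            "p": 0.0 if np.isinf(bsr) else float(2 * stats.norm.sf(abs(bsr))),
            "sessions": tuple(contrast_sessions),
        }
    return result
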