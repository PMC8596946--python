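"""Low-rank matrix completion by iterative soft-thresholded SVD.

Missing sessions leave NaN blocks in the athletes-by-features matrix of
difference scores (features are session-concatenated voxels by default).
The completion iterates Z <- SVT_lambda(P_obs(X) + P_miss(Z)), where SVT
soft-thresholds the singular values by lambda, which monotonically
decreases the objective 0.5*||P_obs(X - Z)||_F^2 + lambda*||Z||_*.  The
soft threshold is chosen by repeated random holdout cross-validation of
reconstruction error on hidden observed entries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin


def _svd_econ(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Economy SVD, routed through the small Gram matrix when M is wide.

    For an n x p matrix with p >> n the eigendecomposition of M M^T costs
    O(n^2 p) with a tiny O(n^3) tail, far cheaper than a direct SVD; the
    right singular vectors are recovered as V = M^T U / s.
    """
    n, p = M.shape
    if p < 4 * n:
        return np.linalg.svd(M, full_matrices=False)
    G = M @ M.T
    evals, U = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1]
    evals, U = evals[order], U[:, order]
    s = np.sqrt(np.maximum(evals, 0.0))
    safe = np.where(s > 0, s, 1.0)
    Vt = (U.T @ M) / safe[:, None]
    return U, s, Vt


def _check_pattern(observed: np.ndarray) -> None:
    if not observed.any():
        raise ValueError("matrix has no observed entries")
    if (~observed).sum() and (
        (observed.sum(axis=1) == 0).any() or (observed.sum(axis=0) == 0).any()
    ):
        raise ValueError("every row and column needs at least one observed entry")


class SoftImpute(BaseEstimator, TransformerMixin):
    """SOFT-IMPUTE matrix completion with a fixed soft threshold ``lam``.

    ``transform`` returns the input with observed entries untouched and
    missing entries filled from the converged low-rank iterate Z.

    Parameters
    ----------
    lam : soft threshold applied to the singular values (>= 0).
    max_rank : optional cap on the rank of the SVT step.
    tol : relative Frobenius-change convergence tolerance.
    max_iter : sweep limit; non-convergence warns and keeps the last iterate.
    init : optional warm-start matrix for the missing entries.

    Attributes
    ----------
    n_iter_ : sweeps actually run.
    objective_ : objective value per sweep (non-increasing).
    singular_values_ : soft-thresholded singular values of the final Z.
    rank_ : number of nonzero thresholded singular values.
    """

    def __init__(self, lam: float = 0.0, max_rank: int | None = None,
                 tol: float = 1e-5, max_iter: int = 500,
                 init: np.ndarray | None = None):
        self.lam = lam
        self.max_rank = max_rank
        self.tol = tol
        self.max_iter = max_iter
        self.init = init

    def fit(self, X: np.ndarray, y=None) -> "SoftImpute":
        if self.lam < 0:
            raise ValueError("lam must be non-negative")
        X = np.asarray(X, dtype=float)
        observed = ~np.isnan(X)
        _check_pattern(observed)
        X_obs = np.where(observed, X, 0.0)

        if self.init is not None:
            Z = np.where(observed, X_obs, np.asarray(self.init, float))
        else:
            Z = X_obs.copy()

        objective = []
        s_thr = None
        for sweep in range(self.max_iter):
            M = np.where(observed, X_obs, Z)
            u, s, vt = _svd_econ(M)
            s_thr = np.maximum(s - self.lam, 0.0)
            if self.max_rank is not None:
                s_thr[self.max_rank:] = 0.0
            k = int(np.count_nonzero(s_thr))
            Z_new = (u[:, :k] * s_thr[:k]) @ vt[:k]
            resid = X_obs - np.where(observed, Z_new, 0.0)
            obj = 0.5 * float((resid[observed] ** 2).sum()) \
                + self.lam * float(s_thr.sum())
            if objective and obj > objective[-1] * (1 + 1e-10) + 1e-12:
                warnings.warn(
                    f"soft-impute objective increased at sweep {sweep}",
                    stacklevel=2,
                )
            objective.append(obj)
            diff = float(np.linalg.norm(Z_new - Z))
            denom = max(float(np.linalg.norm(Z)), float(np.linalg.norm(Z_new)))
            change = 0.0 if denom == 0 else diff / denom
            Z = Z_new
            if change < self.tol or not (~observed).any():
                break
        else:
            warnings.warn(
                f"soft-impute did not converge in {self.max_iter} sweeps",
                stacklevel=2,
            )

        self.n_iter_ = len(objective)
        self.objective_ = np.asarray(objective)
        self.singular_values_ = s_thr
        self.rank_ = int(np.count_nonzero(s_thr))
        self.Z_ = Z
        self.observed_ = observed
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        return np.where(np.isnan(X), self.Z_, X)

    def fit_transform(self, X: np.ndarray, y=None, **fit_params) -> np.ndarray:
        self.fit(X)
        X = np.asarray(X, float)
        return np.where(~np.isnan(X), X, self.Z_)


def soft_impute(
    matrix: np.ndarray,
    lam: float,
    tol: float = 1e-5,
    max_iter: int = 500,
    max_rank: int | None = None,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """Complete a matrix with NaN missing entries at soft threshold ``lam``."""
    return SoftImpute(lam=lam, max_rank=max_rank, tol=tol,
                      max_iter=max_iter, init=init).fit_transform(matrix)


@dataclass
class ImputationModel:
    """A chosen soft threshold with its cross-validation record."""

    chosen_lambda: float
    lambda_grid: np.ndarray = field(default_factory=lambda: np.zeros(0))
    cv_errors: np.ndarray = field(default_factory=lambda: np.zeros(0))
    n_iter: int = 0
    holdout_frac: float = 0.05
    seed: int | None = None
    tol: float = 1e-5
    max_rank: int | None = None

    def __post_init__(self) -> None:
        if self.lambda_grid.size and self.cv_errors.size:
            best = self.lambda_grid[int(np.argmin(self.cv_errors))]
            if not np.isclose(best, self.chosen_lambda):
                raise ValueError("chosen_lambda must minimize the CV curve")


def default_lambda_grid(matrix: np.ndarray, n_points: int = 15) -> np.ndarray:
    """Log-spaced grid from the largest singular value of the zero-filled
    matrix down two decades (descending, natural warm-start order)."""
    filled = np.where(np.isnan(matrix), 0.0, matrix)
    s_max = float(np.linalg.svd(filled, compute_uv=False)[0])
    if s_max <= 0:
        raise ValueError("matrix has no signal to scale a lambda grid")
    return np.geomspace(s_max, s_max / 100.0, n_points)


def select_lambda_cv(
    matrix: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    n_iter: int = 200,
    holdout_frac: float = 0.05,
    seed: int | None = None,
    tol: float = 1e-4,
    max_iter: int = 200,
    max_rank: int | None = None,
) -> ImputationModel:
    """Choose the soft threshold by repeated random-holdout cross-validation.

    Each of ``n_iter`` repeats hides a random ``holdout_frac`` of the
    observed entries (redrawn if a row or column would lose its last
    observation), imputes at every grid value (warm-started down the
    descending grid), and scores squared error on the hidden entries.  The
    chosen lambda minimizes the mean curve.  Deterministic given ``seed``.
    """
    matrix = np.asarray(matrix, dtype=float)
    observed = ~np.isnan(matrix)
    _check_pattern(observed)
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(matrix)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise ValueError("lambda grid is empty")
    order = np.argsort(lambda_grid)[::-1]          # impute largest-first
    rng = np.random.default_rng(seed)
    obs_idx = np.argwhere(observed)
    n_hold = max(1, int(round(holdout_frac * len(obs_idx))))

    errors = np.zeros((n_iter, lambda_grid.size))
    for rep in range(n_iter):
        for _ in range(100):
            sel = rng.choice(len(obs_idx), size=n_hold, replace=False)
            trial = observed.copy()
            trial[tuple(obs_idx[sel].T)] = False
            if trial.any(axis=1).all() and trial.any(axis=0).all():
                break
        else:
            raise ValueError(
                "could not draw a holdout keeping all rows/columns observed"
            )
        X_train = np.where(trial, matrix, np.nan)
        hidden = tuple(obs_idx[sel].T)
        truth = matrix[hidden]
        init = None
        for gi in order:
            model = SoftImpute(lam=float(lambda_grid[gi]), tol=tol,
                               max_iter=max_iter, max_rank=max_rank,
                               init=init).fit(X_train)
            errors[rep, gi] = float(np.mean((model.Z_[hidden] - truth) ** 2))
            init = model.Z_
    mean_err = errors.mean(axis=0)
    chosen = float(lambda_grid[int(np.argmin(mean_err))])
    return ImputationModel(
        chosen_lambda=chosen, lambda_grid=lambda_grid, cv_errors=mean_err,
        n_iter=n_iter, holdout_frac=holdout_frac, seed=seed, tol=tol,
        max_rank=max_rank,
    )
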