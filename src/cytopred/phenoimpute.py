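"""Matrix-completion imputation of missing cytokine responses.

SoftImpute: iterative soft-thresholding of singular values under a
nuclear-norm penalty lambda. Candidate penalties are sigma_1/K for K in a
fixed grid, tuned by repeatedly masking one observed value per column and
scoring the masked-cell mean squared error. Imputed traits feed the GWAS
stage only; prediction models always use complete cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ImputeConfig:
    k_grid: tuple = (1.5, 2.0, 4.0, 10.0, 50.0, 100.0)
    n_mask_repeats: int = 100   # desk-scale default; production runs use 1000
    max_iter: int = 500
    tol: float = 1e-5           # relative Frobenius change of the missing block
    seed: int = 0

    def __post_init__(self):
        if any(k <= 1 for k in self.k_grid):
            raise ValueError("k_grid values must exceed 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class ImputeResult:
    completed: np.ndarray
    lam: float
    n_iter: int
    converged: bool
    objective_trajectory: list = field(default_factory=list)


def filter_missing_individuals(panel: pd.DataFrame,
                               max_missing_fraction: float = 0.8
                               ) -> pd.DataFrame:
    """Drop individuals with strictly more than the allowed fraction of
    missing cytokine entries."""
    frac = panel.isna().mean(axis=1)
    keep = frac <= max_missing_fraction
    if not keep.any():
        raise ValueError("every individual exceeds the missingness limit")
    return panel.loc[keep]


def _objective(M: np.ndarray, X: np.ndarray, obs: np.ndarray, lam: float
               ) -> float:
    resid = (X - M)[obs]
    nuclear = np.linalg.svd(M, compute_uv=False).sum()
    return 0.5 * float(resid @ resid) + lam * nuclear


def soft_impute(X_with_missing, lam: float, config: ImputeConfig = None
                ) -> ImputeResult:
    """Nuclear-norm-penalized matrix completion by iterated soft-thresholded
    SVD.

    Missing cells start at 0 (inputs are assumed standardized); each
    iteration shrinks every singular value of the current completion by
    lambda (floored at 0), rebuilds, and restores the observed cells.
    Stops when the relative Frobenius change of the missing-cell block
    falls below tol, or flags non-convergence at max_iter (not fatal).
    Observed entries of the output equal the input's observed entries
    exactly.
    """
    if config is None:
        config = ImputeConfig()
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    X = np.asarray(X_with_missing, dtype=float)
    obs = ~np.isnan(X)
    miss = ~obs
    if not miss.any():
        return ImputeResult(completed=X.copy(), lam=lam, n_iter=0,
                            converged=True)

    Z = np.where(obs, X, 0.0)
    trajectory = []
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        s_shrunk = np.maximum(s - lam, 0.0)
        M = (U * s_shrunk) @ Vt
        trajectory.append(0.5 * float(((X - M)[obs] ** 2).sum())
                          + lam * s_shrunk.sum())
        Z_new = np.where(obs, X, M)
        prev = Z[miss]
        delta = np.linalg.norm(Z_new[miss] - prev)
        denom = max(np.linalg.norm(prev), 1e-12)
        Z = Z_new
        if delta / denom < config.tol:
            converged = True
            break
    if not converged:
        logger.warning("soft_impute: not converged after %d iterations",
                       config.max_iter)
    return ImputeResult(completed=Z, lam=lam, n_iter=it, converged=converged,
                        objective_trajectory=trajectory)


def tune_lambda(X_with_missing, config: ImputeConfig = None):
    """Select lambda = sigma_1/K over the K grid by masked-value MSE.

    Per repeat, one observed value per column is masked uniformly at
    random; each candidate lambda imputes the masked matrix and the MSE on
    the masked cells is recorded. Returns (best lambda, per-lambda table).
    """
    if config is None:
        config = ImputeConfig()
    X = np.asarray(X_with_missing, dtype=float)
    obs = ~np.isnan(X)
    if (obs.sum(axis=0) < 2).any():
        raise ValueError("every column needs at least 2 observed values")
    sigma1 = np.linalg.svd(np.where(obs, X, 0.0), compute_uv=False)[0]
    lambdas = [sigma1 / k for k in config.k_grid]

    rng = np.random.default_rng(config.seed)
    mse = np.zeros((config.n_mask_repeats, len(lambdas)))
    for r in range(config.n_mask_repeats):
        Xm = X.copy()
        cells = []
        for j in range(X.shape[1]):
            rows = np.flatnonzero(obs[:, j])
            i = rows[rng.integers(len(rows))]
            Xm[i, j] = np.nan
            cells.append((i, j))
        rows_idx = np.array([c[0] for c in cells])
        cols_idx = np.array([c[1] for c in cells])
        truth = X[rows_idx, cols_idx]
        for li, lam in enumerate(lambdas):
            res = soft_impute(Xm, lam, config)
            imputed = res.completed[rows_idx, cols_idx]
            mse[r, li] = float(np.mean((imputed - truth) ** 2))

    table = pd.DataFrame({"K": list(config.k_grid), "lambda": lambdas,
                          "mean_mse": mse.mean(axis=0)})
    best = float(table.loc[table["mean_mse"].idxmin(), "lambda"])
    return best, table


def rmse_skill(completed, truth, mask) -> pd.Series:
    """Per-column RMSE skill vs mean imputation: 1 - RMSE_model/RMSE_mean.

    ``mask`` marks the cells that were hidden from the imputer; ``truth``
    holds their true values (simulation setting). The mean baseline
    imputes each masked cell with its column's observed mean. Columns with
    RMSE_mean = 0 are reported missing.
    """
    C = np.asarray(completed, dtype=float)
    T = np.asarray(truth, dtype=float)
    M = np.asarray(mask, dtype=bool)
    cols = (truth.columns if isinstance(truth, pd.DataFrame)
            else pd.RangeIndex(T.shape[1]))
    out = {}
    for j, col in enumerate(cols):
        m = M[:, j]
        if not m.any():
            out[col] = np.nan
            continue
        col_mean = T[~m, j].mean()
        rmse_model = np.sqrt(np.mean((C[m, j] - T[m, j]) ** 2))
        rmse_mean = np.sqrt(np.mean((col_mean - T[m, j]) ** 2))
        out[col] = 1.0 - rmse_model / rmse_mean if rmse_mean > 0 else np.nan
    return pd.Series(out)
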