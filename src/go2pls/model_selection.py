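"""Cross-validation for the numbers of components and the sparsity levels.

Three procedures, mirroring how the model is tuned in practice:

* :func:`cv_orthogonal` — 2-D grid search over (Kx, Ky) at fixed K, scored by
  held-out prediction of U from T and T from U through the inner relation.
* :func:`cv_joint` — sequential search over K at fixed (Kx, Ky), scored by
  held-out MSE of predicting X -> Y plus Y -> X.
* :func:`cv_sparsity` — grid search over the numbers of retained groups
  (h_x, h_y), scored by the held-out covariance of each estimated joint score
  pair, with the one-standard-error rule for a sparser, more stable choice.

Fold assignment is a deterministic function of (N, folds, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .blocks import GroupStructure, OmicsBlock
from .core import OverPenalizedError, PenaltySpec
from .model import fit as _fit, transform

logger = logging.getLogger(__name__)

__all__ = ["CVResult", "fold_assignment", "cv_orthogonal", "cv_joint", "cv_sparsity"]


@dataclass
class CVResult:
    """Evaluated CV grid with per-cell mean and standard error.

    ``direction`` is ``"min"`` or ``"max"``; ``best`` is the arg-optimum of
    ``criterion_mean`` over valid cells, ``best_one_se`` the sparsest cell
    within one standard error of it (populated by :func:`cv_sparsity`).
    """

    grid: list[dict]
    criterion_mean: np.ndarray
    criterion_se: np.ndarray
    per_fold: np.ndarray
    valid: np.ndarray
    folds: int
    seed: int
    direction: str
    best: dict
    best_one_se: dict | None = None
    flat: bool = False
    notes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per grid cell x fold."""
        rows = []
        for i, cell in enumerate(self.grid):
            for f in range(self.folds):
                rows.append({**cell, "fold": f, "criterion": self.per_fold[i, f],
                             "valid": bool(self.valid[i])})
        return pd.DataFrame(rows)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for i, cell in enumerate(self.grid):
            rows.append({**cell, "criterion_mean": self.criterion_mean[i],
                         "criterion_se": self.criterion_se[i],
                         "valid": bool(self.valid[i])})
        return pd.DataFrame(rows)


def fold_assignment(n: int, folds: int, seed: int) -> list[np.ndarray]:
    """Deterministic K-fold split: a seeded permutation cut into ``folds`` parts."""
    if folds < 2:
        raise ValueError("folds must be at least 2")
    if folds > n:
        raise ValueError(f"cannot make {folds} folds from {n} samples")
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(part) for part in np.array_split(perm, folds)]


def _as_array(X) -> np.ndarray:
    if isinstance(X, OmicsBlock):
        return X.data
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def _evaluate_grid(X, Y, grid, folds, seed, fit_kwargs_of, criterion, direction):
    """Shared grid x folds evaluation loop.

    ``fit_kwargs_of(cell)`` builds the :func:`go2pls.model.fit` arguments for
    one grid cell; ``criterion(fitres, Xte, Yte)`` scores one held-out fold.
    A cell where any fold raises is marked invalid and excluded.
    """
    X = _as_array(X)
    Y = _as_array(Y)
    n = X.shape[0]
    assignments = fold_assignment(n, folds, seed)
    per_fold = np.full((len(grid), folds), np.nan)
    valid = np.ones(len(grid), dtype=bool)
    notes: list[str] = []
    for i, cell in enumerate(grid):
        for f, test_ix in enumerate(assignments):
            train_ix = np.setdiff1d(np.arange(n), test_ix)
            try:
                fitres = _fit(X[train_ix], Y[train_ix], **fit_kwargs_of(cell))
                per_fold[i, f] = criterion(fitres, X[test_ix], Y[test_ix])
            except (ValueError, OverPenalizedError, np.linalg.LinAlgError) as exc:
                valid[i] = False
                msg = f"cell {cell} fold {f} infeasible: {exc}"
                notes.append(msg)
                logger.warning(msg)
                break
    mean = np.nanmean(np.where(valid[:, None], per_fold, np.nan), axis=1)
    se = np.nanstd(np.where(valid[:, None], per_fold, np.nan), axis=1, ddof=1)
    se = se / np.sqrt(folds)
    if not valid.any():
        raise ValueError("every grid cell was infeasible")
    masked = np.where(valid, mean, np.inf if direction == "min" else -np.inf)
    best_ix = int(np.argmin(masked) if direction == "min" else np.argmax(masked))
    spread = np.nanmax(mean[valid]) - np.nanmin(mean[valid])
    scale = max(abs(np.nanmean(mean[valid])), 1e-12)
    flat = bool(len(grid) > 1 and spread < 0.01 * scale)
    if flat:
        notes.append("criterion is nearly flat across the grid; selection is weakly determined")
        logger.warning(notes[-1])
    return per_fold, mean, se, valid, best_ix, flat, notes


def cv_orthogonal(
    X, Y, K_fixed: int, kx_grid, ky_grid, folds: int = 5, seed: int = 0
) -> CVResult:
    """Grid search over (Kx, Ky) at fixed K.

    Scores each cell by the held-out error of predicting U from T through B_T
    plus T from U through B_U, each normalised by the held-out score variance
    so cells with different filtering are on a common scale; minimised.
    Better orthogonal filtering gives joint scores that track each other more
    closely on new samples; on structureless data the normalised criterion is
    roughly flat (near its ceiling) and a flatness warning is logged.
    """
    grid = [{"kx": int(kx), "ky": int(ky)} for kx in kx_grid for ky in ky_grid]
    if not grid:
        raise ValueError("empty grid")

    def kwargs_of(cell):
        return {"K": K_fixed, "Kx": cell["kx"], "Ky": cell["ky"]}

    def crit(fitres, Xte, Yte):
        T = transform(fitres, Xte, side="x")
        U = transform(fitres, Yte, side="y")
        var_u = float(np.mean((U - U.mean(axis=0)) ** 2))
        var_t = float(np.mean((T - T.mean(axis=0)) ** 2))
        return (float(np.mean((U - T @ fitres.B_T) ** 2)) / max(var_u, 1e-300)
                + float(np.mean((T - U @ fitres.B_U) ** 2)) / max(var_t, 1e-300))

    per_fold, mean, se, valid, best_ix, flat, notes = _evaluate_grid(
        X, Y, grid, folds, seed, kwargs_of, crit, "min"
    )
    # one-SE rule: fewest orthogonal components within one SE of the minimum
    cutoff = mean[best_ix] + se[best_ix]
    candidates = [
        ((grid[i]["kx"] + grid[i]["ky"], grid[i]["kx"], grid[i]["ky"]), i)
        for i in range(len(grid)) if valid[i] and mean[i] <= cutoff
    ]
    best_one_se = grid[min(candidates)[1]]
    return CVResult(grid=grid, criterion_mean=mean, criterion_se=se,
                    per_fold=per_fold, valid=valid, folds=folds, seed=seed,
                    direction="min", best=grid[best_ix],
                    best_one_se=best_one_se, flat=flat, notes=notes)


def cv_joint(
    X, Y, Kx: int, Ky: int, k_grid, folds: int = 5, seed: int = 0,
    early_stop: bool = True,
) -> CVResult:
    """Sequential search over the number of joint components K.

    Scores each K by held-out MSE(X -> Y) + MSE(Y -> X); minimised.  With
    ``early_stop`` the search walks the sorted grid and stops after the
    criterion has increased twice in a row (two-step patience against local
    bumps); the stop is logged and the full grid is available via
    ``early_stop=False``.
    """
    ks = sorted(int(k) for k in k_grid)
    if not ks:
        raise ValueError("empty grid")
    X = _as_array(X)
    Y = _as_array(Y)
    n = X.shape[0]
    assignments = fold_assignment(n, folds, seed)
    from .model import predict

    grid: list[dict] = []
    per_fold_rows = []
    valid_rows = []
    notes: list[str] = []
    increases = 0
    prev_mean = None
    for K in ks:
        row = np.full(folds, np.nan)
        ok = True
        for f, test_ix in enumerate(assignments):
            train_ix = np.setdiff1d(np.arange(n), test_ix)
            try:
                fitres = _fit(X[train_ix], Y[train_ix], K=K, Kx=Kx, Ky=Ky)
                row[f] = float(
                    np.mean((predict(fitres, X[test_ix], "x_to_y") - Y[test_ix]) ** 2)
                    + np.mean((predict(fitres, Y[test_ix], "y_to_x") - X[test_ix]) ** 2)
                )
            except (ValueError, np.linalg.LinAlgError) as exc:
                ok = False
                msg = f"K={K} fold {f} infeasible: {exc}"
                notes.append(msg)
                logger.warning(msg)
                break
        grid.append({"k": K})
        per_fold_rows.append(row)
        valid_rows.append(ok)
        if ok:
            m = float(np.mean(row))
            if prev_mean is not None and m > prev_mean:
                increases += 1
            else:
                increases = 0
            prev_mean = m
            if early_stop and increases >= 2:
                notes.append(f"sequential search stopped after K={K}: "
                             "criterion increased twice in a row")
                logger.info(notes[-1])
                break
    per_fold = np.vstack(per_fold_rows)
    valid = np.array(valid_rows)
    if not valid.any():
        raise ValueError("every K in the grid was infeasible")
    mean = np.where(valid, np.nanmean(per_fold, axis=1), np.nan)
    se = np.where(valid, np.nanstd(per_fold, axis=1, ddof=1) / np.sqrt(folds), np.nan)
    masked = np.where(valid, mean, np.inf)
    best_ix = int(np.argmin(masked))
    cutoff = mean[best_ix] + se[best_ix]
    cand = [(grid[i]["k"], i) for i in range(len(grid))
            if valid[i] and mean[i] <= cutoff]
    best_one_se = grid[min(cand)[1]]
    return CVResult(grid=grid, criterion_mean=mean, criterion_se=se,
                    per_fold=per_fold, valid=valid, folds=folds, seed=seed,
                    direction="min", best=grid[best_ix],
                    best_one_se=best_one_se, notes=notes)


def cv_sparsity(
    X, Y, K: int, Kx: int, Ky: int, hx_grid, hy_grid,
    groups_x: GroupStructure | None = None,
    groups_y: GroupStructure | None = None,
    folds: int = 5, seed: int = 0, one_se: bool = True,
) -> CVResult:
    """Grid search over the numbers of retained groups (h_x, h_y).

    Each cell is scored by the summed empirical covariance of the held-out
    joint score pairs, Σ_k Cov(t̂_k, û_k), computed with training loadings
    after the training model's orthogonal filtering of the held-out data;
    maximised.  ``None`` in a grid means no penalty on that side.  The
    one-standard-error rule returns the sparsest cell (smallest h_x + h_y)
    whose mean criterion is within one SE of the maximum.
    """
    def pen_of(h, groups):
        if h is None:
            return PenaltySpec.none()
        if groups is not None:
            return PenaltySpec.group(groups, keep=int(h))
        return PenaltySpec.sparse(keep=int(h))

    grid = [{"hx": hx, "hy": hy} for hx in hx_grid for hy in hy_grid]
    if not grid:
        raise ValueError("empty grid")

    def kwargs_of(cell):
        return {"K": K, "Kx": Kx, "Ky": Ky,
                "pen_x": pen_of(cell["hx"], groups_x),
                "pen_y": pen_of(cell["hy"], groups_y)}

    def crit(fitres, Xte, Yte):
        T = transform(fitres, Xte, side="x")
        U = transform(fitres, Yte, side="y")
        n_te = T.shape[0]
        cov = 0.0
        for k in range(T.shape[1]):
            t = T[:, k] - T[:, k].mean()
            u = U[:, k] - U[:, k].mean()
            cov += float(t @ u) / (n_te - 1)
        return cov

    per_fold, mean, se, valid, best_ix, flat, notes = _evaluate_grid(
        X, Y, grid, folds, seed, kwargs_of, crit, "max"
    )
    best = grid[best_ix]
    best_one_se = None
    if one_se:
        cutoff = mean[best_ix] - se[best_ix]

        def density(cell):
            hx = cell["hx"] if cell["hx"] is not None else np.inf
            hy = cell["hy"] if cell["hy"] is not None else np.inf
            return (hx + hy, hx, hy)

        candidates = [
            (density(grid[i]), i)
            for i in range(len(grid))
            if valid[i] and mean[i] >= cutoff
        ]
        best_one_se = grid[min(candidates)[1]]
    return CVResult(grid=grid, criterion_mean=mean, criterion_se=se,
                    per_fold=per_fold, valid=valid, folds=folds, seed=seed,
                    direction="max", best=best, best_one_se=best_one_se,
                    flat=flat, notes=notes)
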