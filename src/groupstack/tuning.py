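"""Tuning-parameter grids and K-fold cross-validation.

Grid conventions: 100 log-spaced points for the primary parameter (lambda
or lambda0) from lambda_max down to 1e-4 * lambda_max, and 30 log-spaced
points for secondary parameters (gamma, lambda1, lambda2).  lambda_max is
the smallest value that zeroes every coefficient, computed from the
stationarity conditions on the standardized (and, for group families,
within-group orthonormalized) design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .penalties import (GROUP_FAMILIES, SCALAR_FAMILIES, SUBSET_FAMILIES,
                        PenaltyConfig)
from .solvers import (GroupedDesign, RegularizationPath, _GroupOrthonormalizer,
                      _Standardizer, fit_group_subset, fit_path)

DEFAULT_N_PRIMARY = 100
DEFAULT_N_SECONDARY = 30
DEFAULT_LAMBDA_RATIO = 1e-4


@dataclass
class TuningGrid:
    """Descending primary grid plus an optional secondary grid."""

    primary: np.ndarray
    secondary: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.primary = np.asarray(self.primary, dtype=float)
        if self.primary.size < 1:
            raise ValueError("empty primary grid")
        if np.any(np.diff(self.primary) >= 0):
            raise ValueError("primary grid must be strictly decreasing")
        if np.any(self.primary[:-1] <= 0):
            raise ValueError("primary grid values must be positive")
        if self.secondary is not None:
            self.secondary = np.asarray(self.secondary, dtype=float)


@dataclass
class CVResult:
    """Cross-validation error surface and the selected configuration."""

    mean_errors: np.ndarray            # n_secondary x n_primary (or 1 x .)
    fold_errors: np.ndarray            # K x n_secondary x n_primary
    grid: TuningGrid
    best_config: PenaltyConfig
    best_indices: Tuple[int, int]
    seed: int
    family: str


def lambda_max(design: GroupedDesign, family: str,
               weights: Optional[np.ndarray] = None) -> float:
    """Smallest primary tuning value that sets every coefficient to zero.

    Scalar families: ``max_j |x_j' y / n|`` on the standardized design
    (divided by w_j for the adaptive lasso).  Group families:
    ``max_g ||Q_g' y / n|| / sqrt(m_g)`` on orthonormalized blocks.
    Subset families: the largest per-group L0 entering threshold.
    """
    std = _Standardizer(design)
    n = design.n
    ys = std.ys
    if float(np.ptp(design.y)) == 0.0:
        warnings.warn("response is constant; lambda_max = 0")
        return 0.0
    if family in SCALAR_FAMILIES:
        corr = np.abs(std.Xs.T @ ys) / n
        if family == "alasso":
            if weights is None:
                raise ValueError("alasso lambda_max requires weights")
            w = np.asarray(weights, dtype=float)
            with np.errstate(divide="ignore"):
                vals = np.where(w > 0, corr / w, np.inf)
            vals = vals[np.isfinite(vals)]
            return float(vals.max()) if vals.size else 0.0
        return float(corr.max())
    if family in GROUP_FAMILIES:
        orth = _GroupOrthonormalizer(std, design.group_indices)
        sizes = design.group_sizes
        vals = [np.linalg.norm(Q.T @ ys / n) / np.sqrt(m)
                for Q, m in zip(orth.Q_blocks, sizes)]
        return float(max(vals))
    raise ValueError(f"lambda_max undefined for family {family!r}")


def make_grid(lam_max: float, n_points: int = DEFAULT_N_PRIMARY,
              ratio: float = DEFAULT_LAMBDA_RATIO) -> TuningGrid:
    """Log-spaced descending grid from lam_max to ratio * lam_max."""
    if lam_max <= 0:
        raise ValueError("lam_max must be positive")
    if ratio >= 1:
        raise ValueError("ratio must be < 1")
    if n_points < 1:
        raise ValueError("need at least one grid point")
    if n_points == 1:
        return TuningGrid(np.array([lam_max]))
    vals = np.geomspace(lam_max, ratio * lam_max, n_points)
    return TuningGrid(vals)


def make_gamma_grid(g_min: Optional[float] = None, g_max: float = 100.0,
                    n_points: int = DEFAULT_N_SECONDARY,
                    family: str = "scad") -> TuningGrid:
    """Log-spaced descending grid for the nonconvexity parameter gamma.

    Defaults to [2 + 1e-4, 100] for both SCAD and MCP; SCAD requires
    gamma > 2 and MCP gamma > 1.
    """
    if g_min is None:
        g_min = 2.0 + 1e-4
    floor = 2.0 if family in ("scad", "grscad") else 1.0
    if g_min <= floor:
        raise ValueError(f"gamma grid minimum must exceed {floor} for {family}")
    if n_points == 1:
        return TuningGrid(np.array([g_max]))
    if g_min >= g_max:
        raise ValueError("gamma grid minimum must be below maximum")
    return TuningGrid(np.geomspace(g_max, g_min, n_points))


def make_folds(n: int, K: int = 5, seed: int = 0) -> np.ndarray:
    """Seeded random partition into K near-equal folds (labels 0..K-1)."""
    if K < 2:
        raise ValueError("need at least 2 folds")
    if K > n:
        raise ValueError("more folds than observations")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    # contiguous blocks of the permuted indices; sizes differ by <= 1
    bounds = np.linspace(0, n, K + 1).round().astype(int)
    for k in range(K):
        labels[perm[bounds[k]:bounds[k + 1]]] = k
    return labels


def _path_for(design: GroupedDesign, family: str, lambdas: np.ndarray,
              gamma=None, lambda2=0.0, weights=None, lambda1=0.0,
              tol=1e-5) -> RegularizationPath:
    if family in SUBSET_FAMILIES:
        shrink = {"grsubset": "none", "grsubset_grlasso": "grlasso",
                  "grsubset_ridge": "ridge"}[family]
        return fit_group_subset(design, lambda1=lambda1, shrink_family=shrink,
                                lambda0_grid=lambdas, tol=tol)
    return fit_path(design, family, lambdas, gamma=gamma, lambda2=lambda2,
                    weights=weights, tol=tol)


def alasso_weights(design: GroupedDesign, eps: float = 1e-8) -> np.ndarray:
    """Adaptive-lasso weights 1 / (|ridge estimate| + eps).

    The initial estimate is a cross-validated ridge fit, which is defined
    even when p > n.
    """
    from sklearn.linear_model import RidgeCV
    std = _Standardizer(design)
    alphas = np.geomspace(1e-3, 1e3, 13) * design.n
    model = RidgeCV(alphas=alphas, fit_intercept=False)
    model.fit(std.Xs, std.ys)
    return 1.0 / (np.abs(model.coef_) + eps)


def cross_validate(design: GroupedDesign, family: str, K: int = 5,
                   seed: int = 0, grid: Optional[TuningGrid] = None,
                   n_primary: int = DEFAULT_N_PRIMARY,
                   n_secondary: int = DEFAULT_N_SECONDARY,
                   secondary_mode: str = "fixed",
                   lambda_ratio: float = DEFAULT_LAMBDA_RATIO,
                   tol: float = 1e-3) -> CVResult:
    """K-fold cross-validation over a tuning grid, scored by RMSE.

    Folds are a seeded random partition; per fold the full regularization
    path is fit on the training folds with warm starts and scored on the
    held-out fold.  ``secondary_mode``:

    * ``"fixed"`` — nonconvexity/secondary parameters stay at their
      defaults (SCAD 3.7, MCP 3.0, lambda1/lambda2 as supplied);
    * ``"grid"`` — full nested search over the secondary grid, selecting
      the joint minimizer; ties break toward larger lambda then larger
      gamma (more convex / more parsimonious).
    """
    n = design.n
    if K < 2 or n < K:
        raise ValueError("invalid fold count")
    fold_labels = make_folds(n, K, seed)
    counts = np.bincount(fold_labels, minlength=K)
    if counts.min() < 2:
        raise ValueError("a fold has fewer than 2 observations")

    weights = None
    if family == "alasso":
        weights = alasso_weights(design)

    # primary grid
    if grid is None:
        if family in SUBSET_FAMILIES:
            shrink = {"grsubset": "none", "grsubset_grlasso": "grlasso",
                      "grsubset_ridge": "ridge"}[family]
            ref = fit_group_subset(design, lambda1=0.0, shrink_family=shrink,
                                   grid_size=n_primary, tol=tol)
            primary = ref.lambdas
            # adaptive grids may repeat/stall; enforce strict decrease
            primary = primary[np.concatenate(([True], np.diff(primary) < 0))]
            grid = TuningGrid(primary)
        else:
            lmax = lambda_max(design, family, weights=weights)
            grid = make_grid(lmax * 1.0001, n_primary, lambda_ratio)

    # secondary grid; the grSubset shrinkage strength lambda1 is integral
    # to the grSubset+grLasso / +Ridge estimators and is always tuned
    if family in SUBSET_FAMILIES and family != "grsubset":
        lmax_g = lambda_max(design, "grlasso")
        sec = np.concatenate(([0.0], np.geomspace(1e-3 * lmax_g, lmax_g,
                                                  n_secondary - 1)))
    elif secondary_mode == "grid":
        if family in ("scad", "mcp", "grscad", "grmcp"):
            sec = make_gamma_grid(family=family.replace("gr", ""),
                                  n_points=n_secondary).primary
        elif family == "enet":
            sec = np.concatenate(([0.0], np.geomspace(1e-4, 10.0,
                                                      n_secondary - 1)))
        else:
            sec = np.array([np.nan])
    else:
        sec = np.array([np.nan])
    n_sec = sec.size
    if grid.secondary is None and not np.all(np.isnan(sec)):
        grid.secondary = sec

    lambdas = grid.primary
    fold_err = np.full((K, n_sec, lambdas.size), np.nan)
    for k in range(K):
        tr = np.flatnonzero(fold_labels != k)
        te = np.flatnonzero(fold_labels == k)
        dtr = design.subset(tr)
        Xte, yte = design.X[te], design.y[te]
        w_tr = alasso_weights(dtr) if family == "alasso" else None
        for s in range(n_sec):
            kw = _secondary_kwargs(family, sec[s], secondary_mode)
            path = _path_for(dtr, family, lambdas, weights=w_tr, tol=tol, **kw)
            pred = path.predict(Xte)
            err = np.sqrt(np.mean((yte[:, None] - pred) ** 2, axis=0))
            fold_err[k, s, :len(path)] = err
            if len(path) < lambdas.size:
                fold_err[k, s, len(path):] = err[-1]

    mean_err = fold_err.mean(axis=0)
    # joint minimizer; ties toward larger lambda (later index smaller lam)
    best_flat = None
    best_val = np.inf
    for s in range(n_sec):
        for i in range(lambdas.size):
            v = mean_err[s, i]
            if np.isfinite(v) and v < best_val - 1e-15:
                best_val = v
                best_flat = (s, i)
    if best_flat is None:
        raise RuntimeError("cross-validation produced no finite errors")
    s, i = best_flat
    best_config = _build_config(family, lambdas[i], sec[s], secondary_mode,
                                weights)
    return CVResult(mean_err, fold_err, grid, best_config, (s, i), seed,
                    family)


def _secondary_kwargs(family: str, sec_val: float, mode: str) -> dict:
    if family in ("scad", "mcp", "grscad", "grmcp"):
        return {"gamma": None if mode == "fixed" else float(sec_val)}
    if family == "enet":
        return {"lambda2": 0.0 if mode == "fixed" else float(sec_val)}
    if family in ("grsubset_grlasso", "grsubset_ridge"):
        return {"lambda1": float(sec_val)}
    return {}


def _build_config(family, lam, sec_val, mode, weights) -> PenaltyConfig:
    kw = _secondary_kwargs(family, sec_val, mode)
    if family in SUBSET_FAMILIES:
        return PenaltyConfig(family, lam=0.0, lambda0=float(lam),
                             lambda2=kw.get("lambda1", 0.0))
    return PenaltyConfig(family, lam=float(lam), weights=weights, **kw)


def fit_best(design: GroupedDesign, cv: CVResult, tol: float = 1e-4):
    """Refit the CV-selected configuration on the full design."""
    from .solvers import fit_group_penalized, fit_penalized
    cfg = cv.best_config
    fam = cfg.family
    if fam in SCALAR_FAMILIES:
        w = alasso_weights(design) if fam == "alasso" else None
        cfg = PenaltyConfig(fam, lam=cfg.lam, gamma=cfg.gamma,
                            lambda2=cfg.lambda2, weights=w)
        return fit_penalized(design, cfg, tol=tol)
    if fam in GROUP_FAMILIES:
        return fit_group_penalized(design, cfg, tol=tol)
    if fam in SUBSET_FAMILIES:
        shrink = {"grsubset": "none", "grsubset_grlasso": "grlasso",
                  "grsubset_ridge": "ridge"}[fam]
        s, i = cv.best_indices
        path = fit_group_subset(design, lambda1=cfg.lambda2,
                                shrink_family=shrink,
                                lambda0_grid=cv.grid.primary[:i + 1], tol=tol)
        return path.fits[-1]
    raise ValueError(fam)


def tune_and_fit(design: GroupedDesign, family: str, K: int = 5,
                 seed: int = 0, secondary_mode: str = "fixed",
                 n_primary: int = DEFAULT_N_PRIMARY,
                 n_secondary: int = DEFAULT_N_SECONDARY,
                 cv_tol: float = 1e-3, refit_tol: float = 1e-4):
    """Cross-validate a family and refit the winner on the full data.

    Cross-validation paths use a looser convergence tolerance than the
    final refit: held-out error is insensitive to the last digits of the
    coefficients, while the returned model is polished at ``refit_tol``.
    """
    cv = cross_validate(design, family, K=K, seed=seed,
                        n_primary=n_primary, n_secondary=n_secondary,
                        secondary_mode=secondary_mode, tol=cv_tol)
    fit = fit_best(design, cv, tol=refit_tol)
    return fit, cv
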