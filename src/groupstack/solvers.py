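"""Coordinate-descent solvers for penalized and group-penalized regression.

Three fitting engines share a common standardization layer:

* :func:`fit_penalized` — cyclic coordinate descent for the scalar
  penalties (lasso, SCAD, MCP, elastic net, adaptive lasso);
* :func:`fit_group_penalized` — block coordinate descent for the group
  penalties (grLasso, grSCAD, grMCP) on within-group orthonormalized
  design blocks, so each block update is a closed-form group threshold;
* :func:`fit_group_subset` — L0 group-subset selection, optionally
  combined with group-lasso or ridge shrinkage, fitted over an adaptive
  decreasing grid of the selection penalty lambda0 with warm starts.

All solvers minimize ``(1/(2n)) * ||y - intercept - X beta||^2 + P(beta)``
with an unpenalized intercept handled by centering.  Columns are scaled
to unit variance internally and coefficients mapped back.  The hot loops
live in :mod:`groupstack._kernels`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import _kernels as K
from .penalties import (
    GROUP_FAMILIES,
    SCALAR_FAMILIES,
    SUBSET_FAMILIES,
    PenaltyConfig,
    penalty_value,
)

DEFAULT_TOL = 1e-7
DEFAULT_MAX_ITER = 10_000

_SCALAR_CODE = {"lasso": K.F_LASSO, "scad": K.F_SCAD, "mcp": K.F_MCP,
                "enet": K.F_ENET, "alasso": K.F_ALASSO}
_GROUP_CODE = {"grlasso": K.F_LASSO, "grscad": K.F_SCAD, "grmcp": K.F_MCP}
_SHRINK_CODE = {"none": K.S_NONE, "grlasso": K.S_GRLASSO, "ridge": K.S_RIDGE}


class ConvergenceWarning(UserWarning):
    pass


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class GroupedDesign:
    """Design matrix, response, and a non-overlapping group partition.

    ``groups`` assigns each column a group label; labels need not be
    contiguous blocks of columns (an explicit index map is built).
    """

    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray
    column_names: Optional[List[str]] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.groups = np.asarray(self.groups)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        n, p = self.X.shape
        if self.y.shape[0] != n:
            raise ValueError("y length does not match X rows")
        if n < 2:
            raise ValueError("need at least 2 observations")
        if self.groups.shape[0] != p:
            raise ValueError("group labels must have length p")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.y))):
            raise ValueError("non-finite entries in X or y")
        if self.column_names is not None and len(self.column_names) != p:
            raise ValueError("column_names length mismatch")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def group_labels(self) -> np.ndarray:
        """Unique group labels in first-appearance order."""
        _, idx = np.unique(self.groups, return_index=True)
        return self.groups[np.sort(idx)]

    @property
    def group_indices(self) -> List[np.ndarray]:
        """Column index arrays, one per group, in label order."""
        return [np.flatnonzero(self.groups == g) for g in self.group_labels]

    @property
    def group_sizes(self) -> np.ndarray:
        return np.array([idx.size for idx in self.group_indices])

    @property
    def n_groups(self) -> int:
        return self.group_labels.size

    def subset(self, rows: np.ndarray) -> "GroupedDesign":
        return GroupedDesign(self.X[rows], self.y[rows], self.groups,
                             self.column_names)


@dataclass
class CoefficientFit:
    """A fitted penalized regression model on the original data scale."""

    intercept: float
    beta: np.ndarray
    active_groups: set
    objective: float
    converged: bool
    iterations: int
    config: PenaltyConfig

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.beta.shape[0]:
            raise ValueError("column count mismatch")
        return self.intercept + X @ self.beta

    @property
    def n_selected(self) -> int:
        return int(np.count_nonzero(self.beta))


@dataclass
class RegularizationPath:
    """Fits over a decreasing grid of the primary tuning parameter."""

    configs: List[PenaltyConfig]
    fits: List[CoefficientFit]
    lambdas: np.ndarray
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.fits)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """n_new x n_path prediction matrix."""
        return np.column_stack([f.predict(X) for f in self.fits])


@dataclass
class GroupSubsetState:
    """Snapshot of the group-subset coordinate descent at a grid point."""

    vbar: List[np.ndarray]
    active_set: set
    block_constants: np.ndarray
    alpha: float
    lambda0: float
    lambda1: np.ndarray
    grad_norms: np.ndarray
    group_sizes: np.ndarray


# ---------------------------------------------------------------------------
# standardization / orthonormalization
# ---------------------------------------------------------------------------

class _Standardizer:
    """Center y; center and unit-scale X columns."""

    def __init__(self, design: GroupedDesign):
        X, y = design.X, design.y
        self.x_mean = X.mean(axis=0)
        self.y_mean = y.mean()
        sd = X.std(axis=0)
        self.degenerate = sd <= 1e-12 * (1 + np.abs(self.x_mean))
        self.scale = np.where(self.degenerate, 1.0, sd)
        self.Xs = (X - self.x_mean) / self.scale
        self.Xs[:, self.degenerate] = 0.0
        self.ys = y - self.y_mean

    def unstandardize(self, beta_std: np.ndarray) -> Tuple[float, np.ndarray]:
        beta = beta_std / self.scale
        intercept = self.y_mean - float(self.x_mean @ beta)
        return intercept, beta


class _GroupOrthonormalizer:
    """Within-group orthonormalization on top of standardization.

    For each group block Xg (centered/scaled), computes Tg such that
    Qg = Xg @ Tg satisfies Qg' Qg / n = I on the block's intrinsic rank.
    Coefficients fitted on Q map back via beta_g = Tg @ beta_tilde_g.
    """

    def __init__(self, std: _Standardizer, group_indices: List[np.ndarray]):
        n = std.Xs.shape[0]
        self.group_indices = group_indices
        self.transforms: List[np.ndarray] = []
        self.ranks: List[int] = []
        blocks = []
        for idx in group_indices:
            block = std.Xs[:, idx]
            U, s, Vt = np.linalg.svd(block / np.sqrt(n), full_matrices=False)
            thresh = 1e-10 * (s[0] if s.size and s[0] > 0 else 1.0)
            r = int(np.sum(s > thresh))
            if r < idx.size:
                warnings.warn(
                    f"group with columns {idx.tolist()} is rank deficient "
                    f"({r} < {idx.size}); orthonormalized to intrinsic rank",
                    stacklevel=2)
            T = Vt[:r].T / s[:r]
            self.transforms.append(T)
            self.ranks.append(r)
            blocks.append(block @ T)
        # flat layout for the jitted kernels
        self.starts = np.concatenate(([0], np.cumsum(self.ranks))).astype(np.int64)
        self.Q = np.asfortranarray(np.hstack(blocks)) if blocks else \
            np.zeros((n, 0), order="F")

    @property
    def Q_blocks(self) -> List[np.ndarray]:
        return [self.Q[:, self.starts[g]:self.starts[g + 1]]
                for g in range(len(self.ranks))]

    def split(self, v_flat: np.ndarray) -> List[np.ndarray]:
        return [v_flat[self.starts[g]:self.starts[g + 1]]
                for g in range(len(self.ranks))]

    def back_transform(self, v_flat: np.ndarray, p: int) -> np.ndarray:
        beta_std = np.zeros(p)
        for idx, T, v in zip(self.group_indices, self.transforms,
                             self.split(v_flat)):
            beta_std[idx] = T @ v
        return beta_std


# ---------------------------------------------------------------------------
# scalar coordinate descent
# ---------------------------------------------------------------------------

def _objective_scalar(Xs, ys, beta, config, weights):
    n = Xs.shape[0]
    r = ys - Xs @ beta
    loss = 0.5 * float(r @ r) / n
    lam, fam = config.lam, config.family
    ab = np.abs(beta)
    if fam == "lasso":
        pen = lam * ab.sum()
    elif fam == "alasso":
        pen = lam * float(weights @ ab)
    elif fam == "enet":
        pen = lam * ab.sum() + config.lambda2 * float(beta @ beta)
    else:
        pen = sum(penalty_value(t, config) for t in ab)
    return loss + pen


def fit_penalized(design: GroupedDesign, config: PenaltyConfig,
                  tol: float = DEFAULT_TOL, max_iter: int = DEFAULT_MAX_ITER,
                  _state: Optional[dict] = None,
                  beta_init: Optional[np.ndarray] = None) -> CoefficientFit:
    """Cyclic coordinate descent for the scalar penalty families.

    Full sweeps admit entering coordinates; inner sweeps iterate the
    active set to convergence (the standard active-set strategy).
    ``beta_init`` warm-starts on the standardized scale; ``_state`` lets
    path drivers reuse the standardization.
    """
    if config.family not in SCALAR_FAMILIES:
        raise ValueError(f"{config.family!r} is not a scalar family")
    if _state is not None and "std" in _state:
        std = _state["std"]
    else:
        std = _Standardizer(design)
        if _state is not None:
            _state["std"] = std
            _state["XsF"] = np.asfortranarray(std.Xs)
    XsF = _state["XsF"] if _state is not None else np.asfortranarray(std.Xs)
    ys = std.ys
    n, p = XsF.shape
    weights = (config.weights if config.weights is not None
               else np.ones(p))
    beta = (np.zeros(p) if beta_init is None
            else np.asarray(beta_init, float).copy())
    r = ys - XsF @ beta
    usable = np.flatnonzero(~std.degenerate).astype(np.int64)
    gamma = float(config.gamma) if config.gamma is not None else 0.0
    iters, converged = K.scalar_cd(
        XsF, ys, beta, r, usable, float(config.lam), gamma,
        float(config.lambda2), np.asarray(weights, float),
        _SCALAR_CODE[config.family], float(tol), int(max_iter))
    if not converged:
        warnings.warn("coordinate descent did not converge",
                      ConvergenceWarning)
    intercept, beta_orig = std.unstandardize(beta)
    obj = _objective_scalar(std.Xs, ys, beta, config, weights)
    groups = design.groups
    active_groups = set(np.unique(groups[np.flatnonzero(beta_orig)]).tolist())
    fit = CoefficientFit(intercept, beta_orig, active_groups, obj,
                         bool(converged), int(iters), config)
    if _state is not None:
        _state["beta"] = beta
    return fit


# ---------------------------------------------------------------------------
# block coordinate descent for group penalties
# ---------------------------------------------------------------------------

def _group_lambda(config: PenaltyConfig, m_g: int) -> float:
    return config.lam * np.sqrt(m_g) if config.group_size_scaling else config.lam


def _objective_group(orth, ys, v_flat, config, group_sizes):
    n = ys.shape[0]
    r = ys - orth.Q @ v_flat
    loss = 0.5 * float(r @ r) / n
    pen = 0.0
    for v, m in zip(orth.split(v_flat), group_sizes):
        lam_g = _group_lambda(config, m)
        cfg = PenaltyConfig(config.family, lam=lam_g, gamma=config.gamma,
                            group_size_scaling=False)
        pen += penalty_value(float(np.linalg.norm(v)), cfg)
    return loss + pen


def fit_group_penalized(design: GroupedDesign, config: PenaltyConfig,
                        tol: float = DEFAULT_TOL,
                        max_iter: int = DEFAULT_MAX_ITER,
                        _state: Optional[dict] = None,
                        v_init: Optional[np.ndarray] = None
                        ) -> CoefficientFit:
    """Block coordinate descent for grLasso / grSCAD / grMCP.

    Groups are orthonormalized internally so every block update is the
    closed-form group threshold; the penalty level of group g is
    ``lam * sqrt(m_g)`` unless size scaling is disabled in the config.
    ``_state`` lets path drivers reuse the orthonormalization; ``v_init``
    warm-starts on the orthonormal basis.
    """
    if config.family not in GROUP_FAMILIES:
        raise ValueError(f"{config.family!r} is not a group family")
    if _state is not None and "orth" in _state:
        std, orth = _state["std"], _state["orth"]
    else:
        std = _Standardizer(design)
        orth = _GroupOrthonormalizer(std, design.group_indices)
        if _state is not None:
            _state["std"], _state["orth"] = std, orth
    ys = std.ys
    sizes = design.group_sizes
    G = sizes.size
    v = (np.zeros(orth.starts[-1]) if v_init is None
         else np.asarray(v_init, float).copy())
    r = ys - orth.Q @ v
    lam_g = np.array([_group_lambda(config, m) for m in sizes], dtype=float)
    gamma = float(config.gamma) if config.gamma is not None else 0.0
    iters, converged = K.group_cd(orth.Q, v, r, orth.starts, lam_g, gamma,
                                  _GROUP_CODE[config.family], float(tol),
                                  int(max_iter))
    if not converged:
        warnings.warn("block coordinate descent did not converge",
                      ConvergenceWarning)
    beta_std = orth.back_transform(v, design.p)
    intercept, beta = std.unstandardize(beta_std)
    obj = _objective_group(orth, ys, v, config, sizes)
    labels = design.group_labels.tolist()
    active_groups = {labels[g] for g in range(G)
                     if np.any(v[orth.starts[g]:orth.starts[g + 1]])}
    fit = CoefficientFit(intercept, beta, active_groups, obj,
                         bool(converged), int(iters), config)
    if _state is not None:
        _state["v"] = v
    return fit


# ---------------------------------------------------------------------------
# L0 group-subset coordinate descent
# ---------------------------------------------------------------------------

def next_lambda0(state: GroupSubsetState) -> float:
    """Adaptive-grid step: the next, strictly smaller selection penalty.

    At a converged solution with active set A, the next grid value is
    ``alpha * max_{k not in A} (||grad_k L|| - lambda1_k)_+^2 / (2 p_k c_k)``
    which guarantees at least one new group enters.  Returns -1.0 as a
    "grid exhausted" sentinel when every group is already active.
    """
    G = state.grad_norms.shape[0]
    inactive = [k for k in range(G) if k not in state.active_set]
    if not inactive:
        return -1.0
    vals = [
        max(state.grad_norms[k] - state.lambda1[k], 0.0) ** 2
        / (2.0 * state.group_sizes[k] * state.block_constants[k])
        for k in inactive
    ]
    return float(state.alpha * max(vals))


def fit_group_subset(design: GroupedDesign, lambda1: float = 0.0,
                     shrink_family: str = "none", alpha: float = 0.9,
                     grid_size: int = 100, tol: float = DEFAULT_TOL,
                     max_iter: int = DEFAULT_MAX_ITER,
                     lambda0_grid: Optional[Sequence[float]] = None,
                     _state: Optional[dict] = None) -> RegularizationPath:
    """L0 group-subset selection over an adaptive lambda0 grid.

    Each group k carries an indicator penalty ``lambda0 * 1(v_k != 0)``
    plus a shrinkage term: ``lambda1 * sqrt(p_k) * ||v_k||``
    (``shrink_family='grlasso'``), ``lambda1 * ||v_k||^2`` ('ridge'), or
    none.  Cyclic block coordinate descent on orthonormalized groups
    solves every block subproblem in closed form; the grid starts at the
    smallest lambda0 that keeps all groups at zero and decreases
    adaptively (:func:`next_lambda0`) with warm starts until ``grid_size``
    points or every group is active.

    ``lambda0_grid`` overrides the adaptive grid (cross-validation uses
    this so folds share a common grid).
    """
    if not (0.0 <= alpha < 1.0):
        raise ValueError("alpha must lie in [0, 1)")
    if shrink_family not in _SHRINK_CODE:
        raise ValueError(f"unknown shrink family {shrink_family!r}")
    if _state is not None and "orth" in _state:
        std, orth = _state["std"], _state["orth"]
    else:
        std = _Standardizer(design)
        orth = _GroupOrthonormalizer(std, design.group_indices)
        if _state is not None:
            _state["std"], _state["orth"] = std, orth
    ys = std.ys
    n = ys.shape[0]
    G = design.n_groups
    sizes = design.group_sizes.astype(float)
    cbar = np.ones(G)  # orthonormalized blocks: unit block curvature
    if shrink_family == "grlasso":
        lam1 = lambda1 * np.sqrt(sizes)
    elif shrink_family == "ridge":
        lam1 = np.full(G, float(lambda1))
    else:
        lam1 = np.zeros(G)
    shrink = _SHRINK_CODE[shrink_family]

    v = np.zeros(orth.starts[-1])
    r = ys.copy()

    def grad_norms():
        g = orth.Q.T @ r / n
        return np.array([np.linalg.norm(g[orth.starts[k]:orth.starts[k + 1]])
                         for k in range(G)])

    def entering_threshold(k, gn):
        if shrink_family == "grlasso":
            return max(gn[k] - lam1[k], 0.0) ** 2 / (2.0 * cbar[k])
        if shrink_family == "ridge":
            return gn[k] ** 2 * cbar[k] / (2.0 * (cbar[k] + 2 * lam1[k]))
        return gn[k] ** 2 / (2.0 * cbar[k])

    gn0 = grad_norms()
    lam0_max = max(entering_threshold(k, gn0) for k in range(G))

    def snapshot(lambda0, converged, iters):
        beta_std = orth.back_transform(v, design.p)
        intercept, beta = std.unstandardize(beta_std)
        loss = 0.5 * float(r @ r) / n
        pen = 0.0
        for g in range(G):
            nv = float(np.linalg.norm(v[orth.starts[g]:orth.starts[g + 1]]))
            if nv > 0:
                pen += lambda0
                if shrink_family == "grlasso":
                    pen += lam1[g] * nv
                elif shrink_family == "ridge":
                    pen += lam1[g] * nv * nv
        labels = design.group_labels.tolist()
        active = {labels[g] for g in range(G)
                  if np.any(v[orth.starts[g]:orth.starts[g + 1]])}
        family = {"none": "grsubset", "grlasso": "grsubset_grlasso",
                  "ridge": "grsubset_ridge"}[shrink_family]
        cfg = PenaltyConfig(family, lam=0.0, lambda2=lambda1, lambda0=lambda0)
        return CoefficientFit(intercept, beta, active, loss + pen,
                              bool(converged), int(iters), cfg)

    configs: List[PenaltyConfig] = []
    fits: List[CoefficientFit] = []
    lambdas: List[float] = []

    def solve_at(lam0):
        return K.subset_cd(orth.Q, v, r, orth.starts, float(lam0), lam1,
                           cbar, shrink, float(tol), int(max_iter))

    if lambda0_grid is not None:
        for lam0 in lambda0_grid:
            iters, conv = solve_at(lam0)
            fit = snapshot(lam0, conv, iters)
            configs.append(fit.config)
            fits.append(fit)
            lambdas.append(float(lam0))
    else:
        lam0 = lam0_max
        for _ in range(grid_size):
            iters, conv = solve_at(lam0)
            fit = snapshot(lam0, conv, iters)
            configs.append(fit.config)
            fits.append(fit)
            lambdas.append(lam0)
            active = {g for g in range(G)
                      if np.any(v[orth.starts[g]:orth.starts[g + 1]])}
            state = GroupSubsetState(vbar=orth.split(v), active_set=active,
                                     block_constants=cbar, alpha=alpha,
                                     lambda0=lam0, lambda1=lam1,
                                     grad_norms=grad_norms(),
                                     group_sizes=sizes)
            nxt = next_lambda0(state)
            if nxt < 0 or nxt >= lam0 or nxt <= 1e-12 * max(lam0_max, 1e-300):
                break
            lam0 = nxt
    return RegularizationPath(configs, fits, np.asarray(lambdas),
                              meta={"shrink_family": shrink_family,
                                    "lambda1": lambda1})


# ---------------------------------------------------------------------------
# path fitting over lambda grids (used by cross-validation)
# ---------------------------------------------------------------------------

def fit_path(design: GroupedDesign, family: str, lambdas: Sequence[float],
             gamma: Optional[float] = None, lambda2: float = 0.0,
             weights: Optional[np.ndarray] = None, tol: float = 1e-5,
             max_iter: int = DEFAULT_MAX_ITER) -> RegularizationPath:
    """Warm-started fits along a decreasing lambda grid."""
    lambdas = np.asarray(lambdas, dtype=float)
    configs: List[PenaltyConfig] = []
    fits: List[CoefficientFit] = []
    state: dict = {}
    if family in SCALAR_FAMILIES:
        for lam in lambdas:
            cfg = PenaltyConfig(family, lam=lam, gamma=gamma, lambda2=lambda2,
                                weights=weights)
            fit = fit_penalized(design, cfg, tol, max_iter, _state=state,
                                beta_init=state.get("beta"))
            configs.append(cfg)
            fits.append(fit)
    elif family in GROUP_FAMILIES:
        for lam in lambdas:
            cfg = PenaltyConfig(family, lam=lam, gamma=gamma)
            fit = fit_group_penalized(design, cfg, tol, max_iter,
                                      _state=state, v_init=state.get("v"))
            configs.append(cfg)
            fits.append(fit)
    else:
        raise ValueError(f"fit_path does not handle family {family!r}")
    return RegularizationPath(configs, fits, lambdas)
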