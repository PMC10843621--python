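"""StackingGroup: a stacked ensemble of group-penalized regressions.

Base learners (default: grSubset+grLasso, grLasso, grSCAD) are tuned by
inner cross-validation on each outer training fold and produce out-of-fold
(OOF) predictions, forming an n x B meta-feature matrix the same size as
the training response.  A lasso meta-learner — this package's own solver —
is fit on those meta-features, and every base learner is refit on the full
data for prediction time.  The OOF construction guarantees no observation
is ever predicted by a model whose training data contained it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .evaluation import mae as _mae
from .evaluation import r_squared, rmse
from .penalties import PenaltyConfig
from .solvers import CoefficientFit, GroupedDesign
from .tuning import make_folds, tune_and_fit
from .tuning import cross_validate, fit_best

DEFAULT_BASES = ("grsubset_grlasso", "grlasso", "grscad")


@dataclass
class StackingModel:
    base_families: List[str]
    base_configs: List[PenaltyConfig]
    K: int
    seed: int
    fold_labels: np.ndarray
    meta_features: np.ndarray
    meta_fit: CoefficientFit
    refit_base_fits: List[CoefficientFit]
    split_mode: str = "kfold"

    @property
    def meta_coefficients(self) -> np.ndarray:
        return self.meta_fit.beta

    @property
    def meta_intercept(self) -> float:
        return self.meta_fit.intercept

    def to_json(self) -> str:
        """Serialize configs, folds, and coefficients for predict-later use."""
        def cfg_dict(c: PenaltyConfig) -> dict:
            return {"family": c.family, "lam": c.lam, "gamma": c.gamma,
                    "lambda2": c.lambda2, "lambda0": c.lambda0,
                    "weights": None if c.weights is None else c.weights.tolist()}

        def fit_dict(f: CoefficientFit) -> dict:
            return {"intercept": f.intercept, "beta": f.beta.tolist(),
                    "config": cfg_dict(f.config)}

        doc = {
            "base_families": self.base_families,
            "base_configs": [cfg_dict(c) for c in self.base_configs],
            "K": self.K, "seed": self.seed, "split_mode": self.split_mode,
            "fold_labels": self.fold_labels.tolist(),
            "meta_fit": fit_dict(self.meta_fit),
            "refit_base_fits": [fit_dict(f) for f in self.refit_base_fits],
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "StackingModel":
        doc = json.loads(text)

        def cfg(d):
            w = d.get("weights")
            return PenaltyConfig(d["family"], lam=d["lam"], gamma=d["gamma"],
                                 lambda2=d["lambda2"], lambda0=d["lambda0"],
                                 weights=None if w is None else np.asarray(w))

        def fit(d):
            beta = np.asarray(d["beta"], dtype=float)
            return CoefficientFit(d["intercept"], beta,
                                  set(), np.nan, True, 0, cfg(d["config"]))

        return cls(doc["base_families"], [cfg(c) for c in doc["base_configs"]],
                   doc["K"], doc["seed"], np.asarray(doc["fold_labels"]),
                   np.empty((0, 0)), fit(doc["meta_fit"]),
                   [fit(f) for f in doc["refit_base_fits"]],
                   doc.get("split_mode", "kfold"))


def _fit_base(design: GroupedDesign, family: str, inner_k: int, seed: int,
              **tune_kw) -> Tuple[CoefficientFit, PenaltyConfig]:
    fit, cv = tune_and_fit(design, family, K=inner_k, seed=seed, **tune_kw)
    return fit, cv.best_config


def oof_meta_features(design: GroupedDesign, base_families: Sequence[str],
                      folds: np.ndarray, inner_k: int = 5, seed: int = 0,
                      **tune_kw) -> Tuple[np.ndarray, List[str]]:
    """Out-of-fold prediction matrix Z (n rows, one column per learner).

    Each learner's hyperparameters are re-tuned by inner cross-validation
    within every outer training fold, so no entry of Z depends on its own
    row's response.  A learner that fails on any fold is dropped with a
    warning; at least two must survive.
    """
    n = design.n
    K = int(folds.max()) + 1
    ss = np.random.SeedSequence(seed)
    inner_seeds = ss.generate_state(K * len(base_families)) % (2 ** 31)
    cols: Dict[str, np.ndarray] = {}
    kept: List[str] = []
    for b, fam in enumerate(base_families):
        z = np.full(n, np.nan)
        try:
            for k in range(K):
                tr = np.flatnonzero(folds != k)
                te = np.flatnonzero(folds == k)
                fit, _ = _fit_base(design.subset(tr), fam, inner_k,
                                   int(inner_seeds[b * K + k]), **tune_kw)
                z[te] = fit.predict(design.X[te])
        except Exception as exc:
            warnings.warn(f"base learner {fam!r} failed and was dropped: {exc}")
            continue
        cols[f"{fam}#{b}"] = z
        kept.append(fam)
    if len(kept) < 2:
        raise RuntimeError("fewer than 2 base learners survived OOF fitting")
    Z = np.column_stack([cols[f"{fam}#{b}"] for b, fam in enumerate(base_families)
                         if f"{fam}#{b}" in cols])
    return Z, kept


def _disjoint_split_features(design: GroupedDesign,
                             base_families: Sequence[str],
                             seed: int, inner_k: int,
                             **tune_kw) -> Tuple[np.ndarray, List[str], np.ndarray]:
    """Alternative meta-feature scheme: one disjoint data slice per learner.

    The training rows are partitioned into B non-overlapping slices; each
    learner is trained on all rows outside its slice and predicts its own
    slice, then all learners predict every row from those fits for the
    meta matrix.  Provided for fidelity experiments with the three-way
    split protocol; the K-fold OOF scheme is the default.
    """
    B = len(base_families)
    n = design.n
    parts = make_folds(n, B, seed)
    ss = np.random.SeedSequence(seed + 1)
    seeds = ss.generate_state(B) % (2 ** 31)
    Z = np.empty((n, B))
    for b, fam in enumerate(base_families):
        tr = np.flatnonzero(parts != b)
        fit, _ = _fit_base(design.subset(tr), fam, inner_k, int(seeds[b]),
                           **tune_kw)
        Z[:, b] = fit.predict(design.X)
    return Z, list(base_families), parts


def fit_stacking(design: GroupedDesign,
                 base_families: Sequence[str] = DEFAULT_BASES,
                 K: int = 5, seed: int = 0, inner_k: int = 5,
                 split_mode: str = "kfold", meta_family: str = "lasso",
                 **tune_kw) -> StackingModel:
    """Fit the full stacking ensemble.

    1. Build the OOF meta-feature matrix Z from the base learners.
    2. Fit the lasso meta-learner of y on Z (lambda by inner CV, using
       this package's own lasso solver).
    3. Refit every base learner on the full data for prediction time.
    """
    folds = make_folds(design.n, K, seed)
    if split_mode == "kfold":
        Z, kept = oof_meta_features(design, base_families, folds,
                                    inner_k=inner_k, seed=seed, **tune_kw)
    elif split_mode == "disjoint":
        Z, kept, folds = _disjoint_split_features(design, base_families, seed,
                                                  inner_k, **tune_kw)
    else:
        raise ValueError(f"unknown split mode {split_mode!r}")

    meta_design = GroupedDesign(Z, design.y, np.arange(1, Z.shape[1] + 1))
    meta_fit, _ = tune_and_fit(meta_design, meta_family, K=inner_k,
                               seed=seed + 1)
    if not np.any(meta_fit.beta):
        warnings.warn("meta-learner degenerated to an intercept-only model")

    ss = np.random.SeedSequence(seed + 2)
    refit_seeds = ss.generate_state(len(kept)) % (2 ** 31)
    refits: List[CoefficientFit] = []
    configs: List[PenaltyConfig] = []
    for b, fam in enumerate(kept):
        fit, cfg = _fit_base(design, fam, inner_k, int(refit_seeds[b]),
                             **tune_kw)
        refits.append(fit)
        configs.append(cfg)
    return StackingModel(list(kept), configs, K, seed, folds, Z, meta_fit,
                         refits, split_mode)


def predict_stacking(model: StackingModel, X_new: np.ndarray) -> np.ndarray:
    """Base predictions on new data combined by the meta-coefficients."""
    X_new = np.asarray(X_new, dtype=float)
    preds = np.column_stack([f.predict(X_new) for f in model.refit_base_fits])
    return model.meta_fit.predict(preds)


def base_learner_diagnostics(design: GroupedDesign,
                             candidate_families: Sequence[str],
                             K: int = 5, seed: int = 0, inner_k: int = 5,
                             rmse_cap_factor: float = 1.25,
                             corr_threshold: float = 0.95,
                             **tune_kw) -> dict:
    """Per-candidate OOF error metrics and residual-correlation diagnostics.

    Candidates should combine strong prediction (CV RMSE within
    ``rmse_cap_factor`` of the best) with diverse errors (pairwise OOF
    residual correlation below ``corr_threshold``); the recommendation is
    built greedily from the best-RMSE candidate.
    """
    if len(candidate_families) < 2:
        raise ValueError("need at least 2 candidates")
    folds = make_folds(design.n, K, seed)
    Z, kept = oof_meta_features(design, candidate_families, folds,
                                inner_k=inner_k, seed=seed, **tune_kw)
    y = design.y
    resid = y[:, None] - Z
    metrics = pd.DataFrame({
        "family": kept,
        "rmse": [rmse(y, Z[:, b]) for b in range(Z.shape[1])],
        "mae": [_mae(y, Z[:, b]) for b in range(Z.shape[1])],
        "r2": [r_squared(y, Z[:, b]) for b in range(Z.shape[1])],
    })
    corr = np.corrcoef(resid.T)
    order = np.argsort(metrics["rmse"].to_numpy(), kind="stable")
    best_rmse = metrics["rmse"].iloc[order[0]]
    chosen: List[int] = []
    for idx in order:
        if metrics["rmse"].iloc[idx] > rmse_cap_factor * best_rmse:
            continue
        if any(abs(corr[idx, j]) >= corr_threshold for j in chosen):
            continue
        chosen.append(int(idx))
    if len(chosen) < 2:
        chosen = [int(order[0]), int(order[1])]
    return {"metrics": metrics, "residual_correlation": corr,
            "recommended": [kept[i] for i in chosen]}
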