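"""Penalty functions and their proximal (thresholding) operators.

Coordinate-descent solvers repeatedly minimize one-dimensional (or one-group)
penalized quadratics.  This module provides the penalty evaluations and the
exact closed-form minimizers of those subproblems for every supported family:

* ``lasso`` / ``alasso`` / ``enet`` — convex, soft-thresholding based;
* ``scad`` / ``mcp`` — nonconvex, nearly unbiased for large coefficients;
* ``grlasso`` / ``grscad`` / ``grmcp`` — group versions acting on the
  Euclidean norm of a coefficient block;
* ``grsubset`` (+ ``grlasso`` / ``ridge`` shrinkage) — an L0 penalty per
  group, handled by the group-subset solver.

All operators minimize ``(denom/2)*b**2 - z*b + P(|b|)`` (equivalently
``(denom/2)*(b - z/denom)**2 + P(|b|)`` up to a constant), the canonical
coordinate subproblem when the objective is ``(1/(2n))*||y - X beta||^2 +
P(beta)`` and columns are standardized (``denom = 1``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

SCALAR_FAMILIES = ("lasso", "scad", "mcp", "enet", "alasso")
GROUP_FAMILIES = ("grlasso", "grscad", "grmcp")
SUBSET_FAMILIES = ("grsubset", "grsubset_grlasso", "grsubset_ridge")
ALL_FAMILIES = SCALAR_FAMILIES + GROUP_FAMILIES + SUBSET_FAMILIES


@dataclass
class PenaltyConfig:
    """Penalty family plus its tuning parameters.

    Parameters
    ----------
    family : str
        One of :data:`ALL_FAMILIES`.
    lam : float
        Primary tuning parameter (lambda).  For grsubset families this is
        unused by the thresholding rules (lambda0 drives selection).
    gamma : float, optional
        Nonconvexity parameter: SCAD requires ``gamma > 2``, MCP requires
        ``gamma > 1``.  Defaults: 3.7 (SCAD), 3.0 (MCP).
    lambda2 : float
        Elastic-net ridge weight, or the shrinkage companion strength
        (lambda1 of the grsubset variants).
    weights : ndarray, optional
        Adaptive-lasso weights, length p, all nonnegative.
    lambda0 : float
        Per-group selection penalty of the grsubset families.
    """

    family: str
    lam: float = 0.0
    gamma: Optional[float] = None
    lambda2: float = 0.0
    weights: Optional[np.ndarray] = None
    lambda0: float = 0.0
    group_size_scaling: bool = True

    def __post_init__(self) -> None:
        if self.family not in ALL_FAMILIES:
            raise ValueError(f"unknown penalty family {self.family!r}")
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")
        if self.lambda2 < 0:
            raise ValueError("lambda2 must be nonnegative")
        if self.lambda0 < 0:
            raise ValueError("lambda0 must be nonnegative")
        if self.gamma is None:
            if self.family in ("scad", "grscad"):
                self.gamma = 3.7
            elif self.family in ("mcp", "grmcp"):
                self.gamma = 3.0
        if self.family in ("scad", "grscad") and not self.gamma > 2:
            raise ValueError("SCAD requires gamma > 2")
        if self.family in ("mcp", "grmcp") and not self.gamma > 1:
            raise ValueError("MCP requires gamma > 1")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if np.any(self.weights < 0):
                raise ValueError("adaptive-lasso weights must be nonnegative")


def penalty_value(t: float, config: PenaltyConfig, weight: float = 1.0) -> float:
    """Evaluate the scalar penalty P(t) at t = |beta| >= 0.

    ``weight`` is the per-coordinate adaptive-lasso weight (ignored by the
    other families).
    """
    if t < 0:
        raise ValueError("penalty argument must be nonnegative")
    lam = config.lam
    fam = config.family
    if fam == "lasso":
        return lam * t
    if fam == "alasso":
        return lam * weight * t
    if fam == "enet":
        return lam * t + config.lambda2 * t * t
    if fam in ("scad", "grscad"):
        a = config.gamma
        if t <= lam:
            return lam * t
        if t < a * lam:
            return -(t * t - 2 * a * lam * t + lam * lam) / (2 * (a - 1))
        return (a + 1) * lam * lam / 2
    if fam in ("mcp", "grmcp"):
        g = config.gamma
        if t <= g * lam:
            return lam * t - t * t / (2 * g)
        return g * lam * lam / 2
    if fam == "grlasso":
        return lam * t
    raise ValueError(f"penalty_value undefined for family {fam!r}")


def soft_threshold(z, lam):
    """Soft-thresholding: sign(z) * max(|z| - lam, 0).

    Unique minimizer of (1/2)(b - z)^2 + lam*|b|.  Works elementwise.
    """
    if np.any(np.asarray(lam) < 0):
        raise ValueError("threshold must be nonnegative")
    return np.sign(z) * np.maximum(np.abs(z) - lam, 0.0)


def _norm_threshold(t: float, config: PenaltyConfig, denom: float) -> float:
    """Minimize (denom/2)*b^2 - t*b + P(b) over b >= 0, for t >= 0.

    This is the magnitude part shared by the scalar and the group
    (radial) thresholding rules for lasso/SCAD/MCP.
    """
    lam = config.lam
    fam = config.family
    if fam in ("lasso", "grlasso", "alasso"):
        return max(t - lam, 0.0) / denom
    if fam in ("scad", "grscad"):
        a = config.gamma
        if a <= 2:
            raise ValueError("SCAD requires gamma > 2")
        if denom - 1.0 / (a - 1) <= 0:
            raise ValueError("SCAD update ill-defined: denom <= 1/(gamma-1)")
        if t <= lam * (denom + 1):
            return max(t - lam, 0.0) / denom
        if t <= a * lam * denom:
            return (t - a * lam / (a - 1)) / (denom - 1.0 / (a - 1))
        return t / denom
    if fam in ("mcp", "grmcp"):
        g = config.gamma
        if g * denom <= 1:
            raise ValueError("MCP update ill-defined: gamma * denom <= 1")
        if t <= g * lam * denom:
            return max(t - lam, 0.0) / (denom - 1.0 / g)
        return t / denom
    raise ValueError(f"no norm threshold for family {fam!r}")


def scalar_threshold(z: float, config: PenaltyConfig, denom: float = 1.0,
                     weight: float = 1.0) -> float:
    """Exact minimizer of the one-dimensional penalized quadratic.

    Solves ``argmin_b (denom/2)*b^2 - z*b + P(|b|)`` for the scalar
    families.  ``weight`` applies only to ``alasso``.
    """
    if denom <= 0:
        raise ValueError("denom must be positive")
    fam = config.family
    if fam not in SCALAR_FAMILIES:
        raise ValueError(f"{fam!r} is not a scalar penalty family")
    az = abs(z)
    if fam == "enet":
        b = max(az - config.lam, 0.0) / (denom + 2 * config.lambda2)
    elif fam == "alasso":
        b = max(az - config.lam * weight, 0.0) / denom
    else:
        b = _norm_threshold(az, config, denom)
    return float(np.sign(z) * b)


def group_threshold(z: np.ndarray, config: PenaltyConfig,
                    denom: float = 1.0) -> np.ndarray:
    """Block thresholding for an orthonormalized group.

    Solves ``argmin_b (denom/2)*||b||^2 - z.b + P(||b||)`` where P is the
    group penalty evaluated at the block norm.  grlasso multiplies z
    radially by ``(1 - lam/||z||)_+ / denom``; grscad/grmcp apply their
    scalar rule to ``||z||`` and rescale radially.  The output is exactly
    the zero vector iff ``||z||`` falls at or below the family's zeroing
    threshold.
    """
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise ValueError("empty group vector")
    if config.family not in GROUP_FAMILIES:
        raise ValueError(f"{config.family!r} is not a group penalty family")
    if denom <= 0:
        raise ValueError("denom must be positive")
    t = float(np.linalg.norm(z))
    if t == 0.0:
        return np.zeros_like(z)
    b = _norm_threshold(t, config, denom)
    if b <= 0.0:
        return np.zeros_like(z)
    return (b / t) * z
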