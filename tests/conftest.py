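"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from groupstack.solvers import GroupedDesign


def make_random_design(n=60, p=12, n_groups=3, seed=0, snr=5.0,
                       n_active_groups=1):
    """Small random grouped regression problem with known active groups."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    groups = np.repeat(np.arange(1, n_groups + 1), p // n_groups)
    if groups.size < p:  # remainder columns join the last group
        groups = np.concatenate([groups,
                                 np.full(p - groups.size, n_groups)])
    beta = np.zeros(p)
    for g in range(1, n_active_groups + 1):
        beta[groups == g] = rng.uniform(0.5, 2.0, size=int(np.sum(groups == g)))
    signal = X @ beta
    noise_sd = np.std(signal) / np.sqrt(snr) if np.std(signal) > 0 else 1.0
    y = signal + rng.standard_normal(n) * noise_sd
    return GroupedDesign(X, y, groups), beta


def standardized_design(n=80, p=10, n_groups=2, seed=0, orthonormal_groups=False):
    """Design whose columns are exactly centered and unit-(population-)scaled.

    With ``orthonormal_groups`` each block additionally satisfies
    X_g' X_g / n = I, so the solver's internal transforms are identity
    (up to an orthogonal rotation) and KKT conditions can be checked in
    the original coordinates.
    """
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    X -= X.mean(axis=0)
    groups = np.repeat(np.arange(1, n_groups + 1), p // n_groups)
    if orthonormal_groups:
        for g in np.unique(groups):
            idx = np.flatnonzero(groups == g)
            q, _ = np.linalg.qr(X[:, idx])
            X[:, idx] = q * np.sqrt(n)
        X -= X.mean(axis=0)  # QR of centered columns keeps them centered
    X /= X.std(axis=0)
    beta = rng.standard_normal(p) * (rng.random(p) < 0.6)
    y = X @ beta + rng.standard_normal(n)
    y -= y.mean()
    return GroupedDesign(X, y, groups)


@pytest.fixture
def small_design():
    design, _ = make_random_design(seed=42)
    return design
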