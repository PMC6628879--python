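"""Shared Moran's I machinery (point weights and raster contiguity both feed
through here)."""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import DegenerateInputError, UndefinedStatisticError


def inverse_distance_weights(coords: np.ndarray) -> np.ndarray:
    """Row-standardised inverse-distance weights with zero self-weight."""
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 2:
        raise DegenerateInputError("need at least 2 locations for spatial weights")
    d = squareform(pdist(coords))
    if np.any((d == 0) & ~np.eye(len(coords), dtype=bool)):
        raise DegenerateInputError("coincident locations give infinite inverse-distance weights")
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    rs = w.sum(axis=1, keepdims=True)
    if np.any(rs == 0):
        raise DegenerateInputError("isolated location with zero total weight")
    return w / rs


def morans_i(values: np.ndarray, weights: np.ndarray) -> float:
    """I = (n/W)·Σᵢⱼ wᵢⱼ zᵢ zⱼ / Σᵢ zᵢ² with z the centred values."""
    z = np.asarray(values, dtype=float)
    z = z - z.mean()
    denom = float(z @ z)
    if denom == 0:
        raise UndefinedStatisticError("Moran's I is undefined for zero-variance values")
    n = len(z)
    w_sum = float(weights.sum())
    return float((n / w_sum) * (z @ weights @ z) / denom)


def moran_permutation_test(
    values: np.ndarray, weights: np.ndarray, n_perm: int = 999, seed: int | None = None
) -> dict:
    """Two-sided permutation test of Moran's I around its null expectation.

    Returns observed I, the analytic expectation −1/(n−1), the permutation
    p-value (with the +1 correction, so min p = 1/(n_perm+1)) and the
    permuted values' mean/sd.
    """
    z = np.asarray(values, dtype=float)
    n = len(z)
    i_obs = morans_i(z, weights)
    expected = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)
    zc = z - z.mean()
    denom = float(zc @ zc)
    perms = np.empty(n_perm)
    scale = n / float(weights.sum())
    for p in range(n_perm):
        zp = rng.permutation(zc)
        perms[p] = scale * (zp @ weights @ zp) / denom
    more_extreme = np.abs(perms - expected) >= np.abs(i_obs - expected) - 1e-15
    p_value = (1.0 + int(more_extreme.sum())) / (n_perm + 1.0)
    return {
        "I": i_obs,
        "expected": expected,
        "p": float(p_value),
        "n_perm": n_perm,
        "perm_mean": float(perms.mean()),
        "perm_sd": float(perms.std(ddof=1)),
    }
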