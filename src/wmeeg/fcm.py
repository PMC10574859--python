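"""Fuzzy C-means clustering.

Minimises J(w, C) = sum_i sum_j w_ij^m ||x_i - c_j||^2 subject to the
memberships of each point summing to 1, by the classical alternating
updates: memberships from the closed-form minimiser given centroids,
centroids as the w^m-weighted means given memberships. The fuzzifier
m > 1 controls how soft the partition is; m -> 1 approaches hard k-means.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["FCMModel", "fcm_membership", "fcm_objective", "fcm_fit"]


@dataclass
class FCMModel:
    centroids: np.ndarray  # (K, d)
    m: float
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.centroids = np.atleast_2d(np.asarray(self.centroids, dtype=float))
        if self.m <= 1:
            raise ValueError("fuzzifier m must be > 1")
        if not np.isfinite(self.centroids).all():
            raise ValueError("centroids must be finite")

    @property
    def K(self) -> int:
        return self.centroids.shape[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "centroids": self.centroids.tolist(),
                "m": self.m,
                "converged": self.converged,
                "n_iter": self.n_iter,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FCMModel":
        d = json.loads(text)
        return cls(np.array(d["centroids"]), d["m"], d["converged"], d["n_iter"])


def _memberships(X: np.ndarray, centroids: np.ndarray, m: float) -> np.ndarray:
    """Closed-form membership update; points that coincide with a centroid
    get membership 1 there (split evenly if they coincide with several)."""
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)  # (n, K)
    zero = d2 <= 0.0
    on_centroid = zero.any(axis=1)
    with np.errstate(divide="ignore"):
        inv = d2 ** (-1.0 / (m - 1.0))
    w = np.empty_like(d2)
    ok = ~on_centroid
    w[ok] = inv[ok] / inv[ok].sum(axis=1, keepdims=True)
    if on_centroid.any():
        w[on_centroid] = zero[on_centroid] / zero[on_centroid].sum(axis=1, keepdims=True)
    return w


def fcm_membership(model: FCMModel, x: np.ndarray) -> np.ndarray:
    """Fuzzy membership degrees of x (single vector or (n, d) array) to
    each centroid; nonnegative, summing to 1 per point."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    W = _memberships(np.atleast_2d(x), model.centroids, model.m)
    return W[0] if single else W


def fcm_objective(X: np.ndarray, W: np.ndarray, C: np.ndarray, m: float) -> float:
    """J(w, C) = sum_ij w_ij^m ||x_i - c_j||^2."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    W = np.atleast_2d(np.asarray(W, dtype=float))
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if W.shape != (X.shape[0], C.shape[0]) or X.shape[1] != C.shape[1]:
        raise ValueError("inconsistent shapes for X, W, C")
    d2 = ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
    return float(((W**m) * d2).sum())


def fcm_fit(
    X: np.ndarray,
    K: int,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int | None = 0,
) -> FCMModel:
    """Alternating optimisation from K distinct seeded sample points;
    stops when the largest centroid displacement falls below tol."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if not 1 <= K <= n:
        raise ValueError(f"need n >= K >= 1, got n={n}, K={K}")
    if K == 1:
        # Eq. for the centroid with all memberships 1: the arithmetic mean.
        return FCMModel(X.mean(axis=0, keepdims=True), m, True, 0)
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=K, replace=False)
    C = X[idx].copy()

    prev_J = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        W = _memberships(X, C, m)
        Wm = W**m
        denom = Wm.sum(axis=0)[:, None]
        # a cluster can lose all weight only in degenerate data; keep its centroid
        new_C = np.where(denom > 0, (Wm.T @ X) / np.where(denom > 0, denom, 1.0), C)
        shift = np.abs(new_C - C).max()
        C = new_C
        J = fcm_objective(X, _memberships(X, C, m), C, m)
        if J > prev_J + 1e-9:
            warnings.warn("FCM objective increased; numerical degeneracy", stacklevel=2)
        prev_J = J
        if shift < tol:
            converged = True
            break
    if np.unique(np.round(C, 9), axis=0).shape[0] < K:
        warnings.warn("degenerate data: centroids collapsed", stacklevel=2)
    return FCMModel(C, m, converged, it)
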