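"""Regression models: epsilon-SVR, the knowledge-based fuzzy SVR, the
multi-linear SVR with fuzzy C-means fusion, and a LASSO baseline.

The epsilon-SVR prediction is the kernel expansion over the support
vectors, f(x) = sum_i (a_i - a_i*) k(x_i, x) + b. Fitting is delegated to
scikit-learn's SMO solver; the fitted expansion (support vectors, dual
coefficients, bias) is extracted into a plain dataclass so that prediction
and text serialisation are self-contained.

The two composites are the contribution of this package:

* Knowledge-based FSVR: z-score the 30 band-ratio features, compress them
  to 10 per-channel working-memory-model satisfaction degrees through the
  fuzzy rule base, and regress ability on those degrees with a Gaussian
  SVR.
* Multi-linear SVR with FCM clustering: a Gaussian SVR fitted on all data
  sets the baseline; points it predicts within an absolute residual
  threshold (strictly below tau = 0.5) form the clustering set; FCM
  partitions that set, one linear SVR is trained per cluster on
  membership-weighted samples, and predictions fuse the experts with the
  membership degrees of the query point. The cluster count K is tuned by
  internal cross-validation over an integer grid (2..10 by default).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import Lasso, LassoCV, LinearRegression
from sklearn.svm import SVR as _SklearnSVR

from .fcm import FCMModel, fcm_fit, fcm_membership
from .features import ZScaler, zscore_fit
from .fuzzy import FuzzyRuleBase, default_rule_base, knowledge_transform

__all__ = [
    "SVRModel",
    "KnowledgeFSVRModel",
    "MultiLinearSVRModel",
    "LassoModel",
    "svr_fit",
    "svr_predict",
    "kfsvr_fit",
    "kfsvr_predict",
    "mlsvr_fit",
    "mlsvr_predict",
    "filter_clustering_set",
    "lasso_fit",
    "lasso_predict",
]


# --------------------------------------------------------------------------
# epsilon-SVR


@dataclass
class SVRModel:
    """Fitted epsilon-SVR dual expansion."""

    support_vectors: np.ndarray  # (n_sv, d)
    dual_coefs: np.ndarray  # (n_sv,) values of (a_i - a_i*)
    bias: float
    kernel: str  # 'gaussian' or 'linear'
    gamma: float | None
    C: float
    epsilon: float

    def __post_init__(self) -> None:
        self.support_vectors = np.atleast_2d(np.asarray(self.support_vectors, float))
        self.dual_coefs = np.asarray(self.dual_coefs, float).ravel()
        if self.kernel not in ("gaussian", "linear"):
            raise ValueError("kernel must be 'gaussian' or 'linear'")
        if np.any(np.abs(self.dual_coefs) > self.C * (1 + 1e-8)):
            raise ValueError("dual coefficients exceed the box constraint C")

    def to_json(self) -> str:
        return json.dumps(
            {
                "support_vectors": self.support_vectors.tolist(),
                "dual_coefs": self.dual_coefs.tolist(),
                "bias": self.bias,
                "kernel": self.kernel,
                "gamma": self.gamma,
                "C": self.C,
                "epsilon": self.epsilon,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SVRModel":
        d = json.loads(text)
        return cls(
            np.array(d["support_vectors"]),
            np.array(d["dual_coefs"]),
            d["bias"],
            d["kernel"],
            d["gamma"],
            d["C"],
            d["epsilon"],
        )


def kernel_matrix(
    A: np.ndarray, B: np.ndarray, kernel: str, gamma: float | None
) -> np.ndarray:
    A = np.atleast_2d(A)
    B = np.atleast_2d(B)
    if kernel == "linear":
        return A @ B.T
    d2 = ((A[:, None, :] - B[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-gamma * d2)


def _resolve_gamma(X: np.ndarray, gamma: float | None) -> float:
    # 1 / (d * var(X)) — scale-free default for the Gaussian kernel
    if gamma is not None:
        return gamma
    v = X.var()
    return 1.0 / (X.shape[1] * v) if v > 0 else 1.0


def svr_fit(
    X: np.ndarray,
    y: np.ndarray,
    kernel: str = "gaussian",
    C: float = 1.0,
    epsilon: float = 0.1,
    gamma: float | None = None,
    sample_weight: np.ndarray | None = None,
) -> SVRModel:
    """Fit epsilon-SVR and return the dual expansion.

    A single training sample (or all-identical labels inside the tube) is
    handled by the solver degenerating to a constant in the tube.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise ValueError("non-finite training inputs")
    if C <= 0 or epsilon < 0:
        raise ValueError("need C > 0 and epsilon >= 0")
    g = _resolve_gamma(X, gamma) if kernel == "gaussian" else None
    if X.shape[0] == 1:
        # degenerate: the tube centred on the single label is optimal
        return SVRModel(X, np.zeros(1), float(y[0]), kernel, g, C, epsilon)
    sk = _SklearnSVR(
        kernel="rbf" if kernel == "gaussian" else "linear",
        C=C,
        epsilon=epsilon,
        gamma=g if kernel == "gaussian" else "scale",
        tol=1e-4,
    )
    if sample_weight is not None:
        sample_weight = np.ascontiguousarray(sample_weight, dtype=float)
    sk.fit(X, y, sample_weight=sample_weight)
    if sk.support_.size == 0:  # everything inside the tube
        return SVRModel(X[:1], np.zeros(1), float(sk.intercept_[0]), kernel, g, C, epsilon)
    return SVRModel(
        sk.support_vectors_,
        sk.dual_coef_.ravel(),
        float(sk.intercept_[0]),
        kernel,
        g,
        C,
        epsilon,
    )


#: shared hyperparameter grid for internal CV: multipliers of the
#: 1/(d * var) gamma heuristic, and box constraints.
SVR_GAMMA_MULTIPLIERS = (0.01, 0.03, 0.1, 0.3, 1.0)
SVR_C_GRID = (1.0, 10.0, 100.0)


def _cv_folds(
    n: int, groups: np.ndarray | None, n_folds: int, rng: np.random.Generator
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Subject-grouped folds when groups are given, plain shuffled folds
    otherwise."""
    if groups is None:
        groups = np.arange(n)
    uniq = np.array(sorted(set(groups)))
    k = min(n_folds, uniq.size)
    perm = rng.permutation(uniq.size)
    fold_of_group = {uniq[perm[i]]: i % k for i in range(uniq.size)}
    fold = np.array([fold_of_group[g] for g in groups])
    return [(fold != f, fold == f) for f in range(k)]


def tune_svr(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray | None = None,
    epsilon: float = 0.1,
    n_folds: int = 3,
    seed: int = 0,
) -> tuple[float, float]:
    """Select (gamma, C) for a Gaussian SVR by internal cross-validation
    MSE over the shared grid; folds are subject-grouped when group labels
    are supplied so trials of one subject never straddle a fold boundary."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    g0 = _resolve_gamma(X, None)
    folds = _cv_folds(X.shape[0], groups, n_folds, np.random.default_rng(seed))
    best = (np.inf, g0, 1.0)
    for gm in SVR_GAMMA_MULTIPLIERS:
        for C in SVR_C_GRID:
            errs = []
            for tr, te in folds:
                if tr.sum() < 2 or te.sum() == 0:
                    continue
                model = svr_fit(
                    X[tr], y[tr], kernel="gaussian", C=C, epsilon=epsilon, gamma=gm * g0
                )
                errs.append(((svr_predict(model, X[te]) - y[te]) ** 2).mean())
            e = float(np.mean(errs)) if errs else np.inf
            if e < best[0]:
                best = (e, gm * g0, C)
    return best[1], best[2]


def svr_predict(model: SVRModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    K = kernel_matrix(np.atleast_2d(X), model.support_vectors, model.kernel, model.gamma)
    out = K @ model.dual_coefs + model.bias
    return float(out[0]) if single else out


def svr_dual_objective(
    K: np.ndarray, y: np.ndarray, beta: np.ndarray, epsilon: float
) -> float:
    """Dual objective in beta_i = a_i - a_i* (to maximise):
    -1/2 b'Kb - eps*||b||_1 + y'b. Exposed for optimiser cross-checks."""
    beta = np.asarray(beta, dtype=float)
    return float(-0.5 * beta @ K @ beta - epsilon * np.abs(beta).sum() + y @ beta)


# --------------------------------------------------------------------------
# knowledge-based FSVR


@dataclass
class KnowledgeFSVRModel:
    """Frozen chain: 30-dim z-scaler -> fuzzy rule base -> 10-dim SVR."""

    scaler: ZScaler
    rulebase: FuzzyRuleBase
    svr: SVRModel

    def to_json(self) -> str:
        return json.dumps(
            {
                "scaler": {"mu": self.scaler.mu.tolist(), "sigma": self.scaler.sigma.tolist()},
                "rulebase": json.loads(self.rulebase.to_json()),
                "svr": json.loads(self.svr.to_json()),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "KnowledgeFSVRModel":
        d = json.loads(text)
        return cls(
            ZScaler(np.array(d["scaler"]["mu"]), np.array(d["scaler"]["sigma"])),
            FuzzyRuleBase.from_json(json.dumps(d["rulebase"])),
            SVRModel.from_json(json.dumps(d["svr"])),
        )


def kfsvr_fit(
    F: np.ndarray,
    y: np.ndarray,
    rb: FuzzyRuleBase | None = None,
    C: float | None = None,
    epsilon: float = 0.1,
    gamma: float | None = None,
    groups: np.ndarray | None = None,
    seed: int = 0,
) -> KnowledgeFSVRModel:
    """Fit the z-scaler on the raw band-ratio features, transform every
    sample to per-channel model-satisfaction degrees, and fit a Gaussian
    SVR on the compressed representation. Unless (gamma, C) are pinned,
    they are selected by internal (grouped) CV on the degree space."""
    F = np.atleast_2d(np.asarray(F, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    rb = rb or default_rule_base()
    scaler = zscore_fit(F)
    G = knowledge_transform(F, scaler, rb)
    if gamma is None or C is None:
        g_cv, c_cv = tune_svr(G, y, groups=groups, epsilon=epsilon, seed=seed)
        gamma = gamma if gamma is not None else g_cv
        C = C if C is not None else c_cv
    svr = svr_fit(G, y, kernel="gaussian", C=C, epsilon=epsilon, gamma=gamma)
    return KnowledgeFSVRModel(scaler, rb, svr)


def kfsvr_predict(model: KnowledgeFSVRModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    G = knowledge_transform(X, model.scaler, model.rulebase)
    return svr_predict(model.svr, G)


# --------------------------------------------------------------------------
# multi-linear SVR with FCM clustering


@dataclass
class MultiLinearSVRModel:
    baseline: SVRModel
    fcm: FCMModel | None
    experts: list[SVRModel] = field(default_factory=list)
    error_threshold: float = 0.5
    chosen_K: int = 0
    cv_mse: dict[int, float] = field(default_factory=dict)


def filter_clustering_set(residuals: np.ndarray, tau: float = 0.5) -> np.ndarray:
    """Indices whose absolute baseline residual is strictly below tau."""
    return np.flatnonzero(np.abs(np.asarray(residuals, dtype=float)) < tau)


def _fit_experts(
    X: np.ndarray,
    y: np.ndarray,
    K: int,
    m: float,
    seed: int,
    C: float,
    epsilon: float,
) -> tuple[FCMModel, list[SVRModel]]:
    fcm = fcm_fit(X, K, m=m, seed=seed)
    W = fcm_membership(fcm, X)
    experts = []
    for k in range(K):
        w = W[:, k]
        if w.sum() <= 1e-12:  # empty cluster: constant fallback expert
            experts.append(SVRModel(X[:1], np.zeros(1), float(y.mean()), "linear", None, C, epsilon))
            continue
        experts.append(
            svr_fit(X, y, kernel="linear", C=C, epsilon=epsilon, sample_weight=w)
        )
    return fcm, experts


def _fuse(fcm: FCMModel, experts: list[SVRModel], X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(X)
    W = fcm_membership(fcm, X)  # (n, K)
    preds = np.column_stack([svr_predict(e, X) for e in experts])
    return (W * preds).sum(axis=1)


def mlsvr_fit(
    X: np.ndarray,
    y: np.ndarray,
    tau: float = 0.5,
    K_grid: "tuple[int, ...] | range" = range(2, 11),
    m: float = 2.0,
    C: float | None = None,
    epsilon: float = 0.1,
    gamma: float | None = None,
    n_cv_folds: int = 5,
    groups: np.ndarray | None = None,
    expert_C: float = 1.0,
    seed: int = 0,
) -> MultiLinearSVRModel:
    """Baseline-filter-cluster-fuse training procedure.

    1. Fit a Gaussian-kernel SVR on all data (the baseline).
    2. Keep the points the baseline predicts with absolute residual
       strictly below tau as the clustering set.
    3. For each K in the grid: FCM-cluster the set, fit one linear SVR per
       cluster with membership sample weights, score by K-fold CV MSE.
    4. Keep the K with the lowest CV MSE, ties going to the smallest K,
       and refit FCM + experts on the full clustering set.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if gamma is None or C is None:
        g_cv, c_cv = tune_svr(X, y, groups=groups, epsilon=epsilon, seed=seed)
        gamma = gamma if gamma is not None else g_cv
        C = C if C is not None else c_cv
    baseline = svr_fit(X, y, kernel="gaussian", C=C, epsilon=epsilon, gamma=gamma)
    residuals = svr_predict(baseline, X) - y
    S = filter_clustering_set(residuals, tau)
    if S.size == 0:
        warnings.warn("clustering set empty; falling back to baseline only", stacklevel=2)
        return MultiLinearSVRModel(baseline, None, [], tau, 0, {})
    Xs, ys = X[S], y[S]

    grid = [int(k) for k in K_grid]
    max_k = max(grid)
    if Xs.shape[0] < max_k:
        warnings.warn(
            f"clustering set has {Xs.shape[0]} points; shrinking K grid", stacklevel=2
        )
        grid = [k for k in grid if k <= Xs.shape[0]]
        if not grid:
            grid = [1]

    rng = np.random.default_rng(seed)
    n = Xs.shape[0]
    folds = max(2, min(n_cv_folds, n))
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[order] = np.arange(n) % folds

    cv_mse: dict[int, float] = {}
    cv_se: dict[int, float] = {}
    for K in grid:
        errs = []
        for f in range(folds):
            tr, te = fold_of != f, fold_of == f
            if tr.sum() < K or te.sum() == 0:
                continue
            fcm, experts = _fit_experts(Xs[tr], ys[tr], K, m, seed, expert_C, epsilon)
            pred = _fuse(fcm, experts, Xs[te])
            errs.append(((pred - ys[te]) ** 2).mean())
        cv_mse[K] = float(np.mean(errs)) if errs else np.inf
        cv_se[K] = float(np.std(errs) / np.sqrt(len(errs))) if errs else np.inf
    # one-standard-error parsimony rule: the smallest K whose CV MSE is
    # within one SE of the best acts as the tie-break toward fewer clusters
    best_K = min(grid, key=lambda k: (cv_mse[k], k))
    threshold = cv_mse[best_K] + cv_se[best_K]
    chosen_K = min(k for k in grid if cv_mse[k] <= threshold)

    fcm, experts = _fit_experts(Xs, ys, chosen_K, m, seed, expert_C, epsilon)
    return MultiLinearSVRModel(baseline, fcm, experts, tau, chosen_K, cv_mse)


def mlsvr_predict(model: MultiLinearSVRModel, X: np.ndarray) -> np.ndarray:
    """Membership-weighted fusion of the expert predictions (a convex
    combination); falls back to the baseline when no experts exist."""
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    X2 = np.atleast_2d(X)
    if model.fcm is None or not model.experts:
        out = svr_predict(model.baseline, X2)
    else:
        out = _fuse(model.fcm, model.experts, X2)
    return float(out[0]) if single else out


# --------------------------------------------------------------------------
# LASSO baseline


@dataclass
class LassoModel:
    coef: np.ndarray
    intercept: float
    mu: np.ndarray
    sigma: np.ndarray
    lam: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.atleast_2d(X) - self.mu) / self.sigma
        return Xs @ self.coef + self.intercept


def lasso_fit(
    X: np.ndarray,
    y: np.ndarray,
    lam: float | None = None,
    n_cv_folds: int = 5,
    seed: int = 0,
) -> LassoModel:
    """L1-penalised least squares on standardized features; when lam is
    None it is chosen by internal CV over a logarithmic grid."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    mu = X.mean(axis=0)
    sigma = X.std(axis=0)
    sigma[sigma == 0] = 1.0
    Xs = (X - mu) / sigma
    if lam is not None:
        if lam == 0:
            ols = LinearRegression().fit(Xs, y)
            return LassoModel(ols.coef_, float(ols.intercept_), mu, sigma, 0.0)
        est = Lasso(alpha=lam, max_iter=50_000).fit(Xs, y)
        return LassoModel(est.coef_, float(est.intercept_), mu, sigma, lam)
    cv = LassoCV(
        alphas=50, cv=n_cv_folds, random_state=seed, max_iter=50_000
    ).fit(Xs, y)
    return LassoModel(cv.coef_, float(cv.intercept_), mu, sigma, float(cv.alpha_))


def lasso_predict(model: LassoModel, X: np.ndarray) -> np.ndarray:
    return model.predict(X)
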