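"""Validation harness: proposition statistics and per-method MSE tables.

Proposition 1 (energy shift): at task onset the alpha band-power ratio
falls while beta and gamma rise. Reported per brain region and band as the
fraction of subjects whose trial- and region-averaged rest-to-task change
has the predicted sign.

Proposition 2 (performance link): performance relates negatively to the
alpha ratio and positively to beta/gamma. Tested per region and band by
simple linear regression of the z-scored performance on the
region-averaged task ratio, with the two-sided t-test p-value on the
slope. P-values are reported uncorrected for multiple comparisons (the
report flags this).

Method comparison uses subject-grouped splits (no subject appears in both
train and test, guarding against person-identification leakage) shared
across methods so the comparison is paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .fuzzy import fuzzy_logic_regress_fit, fuzzy_logic_regress_predict
from .recording import Montage
from . import regress as rg

__all__ = [
    "PropositionReport",
    "proposition1_rates",
    "proposition2_regression",
    "proposition2_table",
    "evaluate_methods",
    "METHODS",
]

BAND_ORDER = ("alpha", "beta", "gamma")
PROP1_SIGNS = {"alpha": -1.0, "beta": +1.0, "gamma": +1.0}


@dataclass
class PropositionReport:
    prop1: pd.DataFrame = field(default_factory=pd.DataFrame)
    prop2: pd.DataFrame = field(default_factory=pd.DataFrame)
    multiple_testing_corrected: bool = False


def proposition1_rates(
    rest: np.ndarray,
    task: np.ndarray,
    montage: Montage | None = None,
    atol: float = 1e-12,
) -> pd.DataFrame:
    """Fraction of subjects satisfying the energy-shift proposition.

    rest: (S, C, 3) per-subject resting ratios; task: (S, T, C, 3)
    per-subject, per-trial task ratios, both in (alpha, beta, gamma) band
    order over the montage's channel order. The change is averaged over
    each subject's trials and over the region's channels before the strict
    sign test.
    """
    montage = montage or Montage()
    rest = np.asarray(rest, dtype=float)
    task = np.asarray(task, dtype=float)
    if rest.ndim != 3 or task.ndim != 4 or rest.shape[0] != task.shape[0]:
        raise ValueError("rest must be (S,C,3) and task (S,T,C,3) with matching S")
    delta = task.mean(axis=1) - rest  # (S, C, 3)
    rows = []
    for region in montage.region_map:
        idx = montage.region_indices(region)
        d = delta[:, idx, :].mean(axis=1)  # (S, 3)
        for bi, band in enumerate(BAND_ORDER):
            # strict inequality, with atol absorbing float rounding so that
            # exactly-equal states never count as satisfying
            ok = PROP1_SIGNS[band] * d[:, bi] > atol
            rows.append({"region": region, "band": band, "rate": float(ok.mean())})
    return pd.DataFrame(rows)


def proposition2_regression(
    ratios: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """Slope and two-sided p-value of the simple linear regression of the
    z-label on a region-averaged band ratio."""
    x = np.asarray(ratios, dtype=float).ravel()
    y = np.asarray(labels, dtype=float).ravel()
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if x.std() == 0:
        raise ValueError("zero-variance regressor")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.pvalue)


def proposition2_table(
    task_ratios: np.ndarray,
    labels: np.ndarray,
    montage: Montage | None = None,
    regions: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Per (region, band): slope sign and p-value of the performance link.

    task_ratios: (n, C, 3) per-record task ratios; labels: (n,) z-scores.
    """
    montage = montage or Montage()
    task_ratios = np.asarray(task_ratios, dtype=float)
    regions = regions or tuple(montage.region_map)
    rows = []
    for region in regions:
        idx = montage.region_indices(region)
        avg = task_ratios[:, idx, :].mean(axis=1)  # (n, 3)
        for bi, band in enumerate(BAND_ORDER):
            slope, p = proposition2_regression(avg[:, bi], labels)
            rows.append(
                {
                    "region": region,
                    "band": band,
                    "slope": slope,
                    "p_value": p,
                    "significant": p < 0.05,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# method comparison


def _fit_predict(method: str, Xtr, ytr, Xte, seed: int, groups_tr=None) -> np.ndarray:
    """Every Gaussian-SVR stage (plain SVR and the composites) selects its
    (gamma, C) by the same internal grouped CV, so the method comparison
    reflects the representations, not tuning asymmetries."""
    if method == "lasso":
        model = rg.lasso_fit(Xtr, ytr, seed=seed)
        return rg.lasso_predict(model, Xte)
    if method == "svr":
        gamma, C = rg.tune_svr(Xtr, ytr, groups=groups_tr, seed=seed)
        model = rg.svr_fit(Xtr, ytr, kernel="gaussian", gamma=gamma, C=C)
        return rg.svr_predict(model, Xte)
    if method == "flr":
        model = fuzzy_logic_regress_fit(Xtr, ytr)
        return fuzzy_logic_regress_predict(model, Xte)
    if method == "mlsvr":
        model = rg.mlsvr_fit(Xtr, ytr, groups=groups_tr, seed=seed)
        return rg.mlsvr_predict(model, Xte)
    if method == "kfsvr":
        model = rg.kfsvr_fit(Xtr, ytr, groups=groups_tr, seed=seed)
        return rg.kfsvr_predict(model, Xte)
    if method == "mean":
        return np.full(np.atleast_2d(Xte).shape[0], np.mean(ytr))
    raise ValueError(f"unknown method {method!r}")


METHODS = ("lasso", "svr", "flr", "mlsvr", "kfsvr")


def _grouped_folds(
    groups: np.ndarray, n_splits: int, rng: np.random.Generator
) -> list[tuple[np.ndarray, np.ndarray]]:
    uniq = np.array(sorted(set(groups)))
    perm = rng.permutation(uniq.size)
    fold_of_group = {uniq[perm[i]]: i % n_splits for i in range(uniq.size)}
    fold = np.array([fold_of_group[g] for g in groups])
    return [(np.flatnonzero(fold != f), np.flatnonzero(fold == f)) for f in range(n_splits)]


def evaluate_methods(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray | None = None,
    methods: tuple[str, ...] = METHODS,
    split: str = "kfold",
    n_splits: int = 5,
    test_fraction: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Held-out MSE per method on identical subject-grouped splits.

    split='kfold' averages over n_splits grouped folds; split='holdout'
    uses a single grouped train/test partition of roughly test_fraction of
    the groups.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if groups is None:
        groups = np.arange(y.size)
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed)
    if split == "kfold":
        folds = _grouped_folds(groups, n_splits, rng)
    elif split == "holdout":
        uniq = np.array(sorted(set(groups)))
        perm = rng.permutation(uniq.size)
        n_test = max(1, int(round(test_fraction * uniq.size)))
        test_groups = set(uniq[perm[:n_test]])
        te = np.array([g in test_groups for g in groups])
        folds = [(np.flatnonzero(~te), np.flatnonzero(te))]
    else:
        raise ValueError("split must be 'kfold' or 'holdout'")

    rows = []
    for method in methods:
        errs = []
        for tr, te in folds:
            pred = _fit_predict(method, X[tr], y[tr], X[te], seed, groups[tr])
            errs.append(float(((pred - y[te]) ** 2).mean()))
        rows.append({"method": method, "mse": float(np.mean(errs))})
    return pd.DataFrame(rows)
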