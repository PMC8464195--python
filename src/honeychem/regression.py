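"""PCR and PLSR prediction of sugar content with RMSECV component selection.

Each sugar is predicted from all other features (the organic grid columns
and, by default, the other three sugars). The latent-component count is
chosen as the argmin of the cross-validated root-mean-square error
(RMSECV, residuals pooled over folds), ties broken toward fewer components
for parsimony. Hold-out evaluation fits on a training split only - all
centring is learned on the training partition - and reports the training
RMSE, the prediction RMSE on the test partition (RMSEP) and R² on both
partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold, train_test_split
from sklearn.pipeline import Pipeline

from .features import FeatureMatrix

METHODS = ("PCR", "PLS")


@dataclass
class RegressionReport:
    method: str
    target: str
    n_components: int
    rmsecv_curve: np.ndarray
    rmse: float  # training-partition RMSE
    rmsep: float  # test-partition RMSE
    r2: float  # test-partition R^2
    r2_train: float
    split: dict
    x_center: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "target": self.target,
            "n_components": self.n_components,
            "rmsecv_curve": self.rmsecv_curve.tolist(),
            "rmse": self.rmse,
            "rmsep": self.rmsep,
            "r2": self.r2,
            "r2_train": self.r2_train,
            "split": self.split,
        }


@dataclass
class MethodComparison:
    target: str
    pcr_components: int
    pls_components: int
    pcr_rmsecv_min: float
    pls_rmsecv_min: float
    pcr_curve: np.ndarray
    pls_curve: np.ndarray

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "pcr_components": self.pcr_components,
            "pls_components": self.pls_components,
            "pcr_rmsecv_min": self.pcr_rmsecv_min,
            "pls_rmsecv_min": self.pls_rmsecv_min,
            "pcr_curve": self.pcr_curve.tolist(),
            "pls_curve": self.pls_curve.tolist(),
        }


def sugar_regression_design(
    matrix: FeatureMatrix, target: str, include_other_sugars: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Predictors and response for one target sugar.

    The target's own column is excluded from the predictors; the other
    three sugars are included by default.
    """
    names = [f.name for f in matrix.features]
    if target not in names:
        raise ValueError(f"target sugar {target!r} not in matrix")
    t = names.index(target)
    keep = [
        i
        for i, f in enumerate(matrix.features)
        if i != t and (include_other_sugars or f.kind != "sugar")
    ]
    return matrix.values[:, keep], matrix.values[:, t]


def _make_model(method: str, n_components: int):
    if method == "PLS":
        return PLSRegression(n_components=n_components, scale=False)
    if method == "PCR":
        return Pipeline(
            [("pca", PCA(n_components=n_components, svd_solver="full")),
             ("ols", LinearRegression())]
        )
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def _predict(model, X: np.ndarray) -> np.ndarray:
    return np.asarray(model.predict(X)).ravel()


def rmsecv_curve(
    X: np.ndarray,
    y: np.ndarray,
    method: str,
    max_components: int,
    folds: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """RMSECV per candidate component count 1 .. max_components.

    For each count the model is fitted on k-1 folds and the squared
    out-of-fold residuals are pooled over all folds before taking the root
    mean. Fold assignment is a deterministic shuffle under the seed and is
    shared across component counts.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if folds < 2:
        raise ValueError("folds must be at least 2")
    if np.ptp(y) == 0:
        raise ValueError("target has zero variance")
    n = len(y)
    cap = min(n - int(np.ceil(n / folds)) - 1, X.shape[1])
    if not 1 <= max_components <= cap:
        raise ValueError(f"max_components must be in [1, {cap}]")
    splits = list(KFold(n_splits=folds, shuffle=True, random_state=seed).split(X))
    curve = np.empty(max_components)
    for c in range(1, max_components + 1):
        sq = np.empty(n)
        for train, test in splits:
            model = _make_model(method, c)
            model.fit(X[train], y[train])
            sq[test] = (y[test] - _predict(model, X[test])) ** 2
        curve[c - 1] = np.sqrt(sq.mean())
    return curve


def select_components(curve: np.ndarray) -> int:
    """Argmin of the RMSECV curve as a component count (ties to fewer)."""
    return int(np.argmin(np.round(curve, 12))) + 1


def fit_evaluate(
    X: np.ndarray,
    y: np.ndarray,
    method: str,
    n_components: int,
    train_fraction: float = 0.7,
    seed: int = 0,
    folds: int = 10,
    stratify_labels=None,
    rmsecv: np.ndarray | None = None,
    target: str = "",
) -> RegressionReport:
    """Fit on a train split only and evaluate on the held-out split.

    Stratification over ``stratify_labels`` is applied when every class has
    at least two members; the 68-sample design has singleton classes, so it
    falls back to a plain shuffled split there. Centring/scaling is learned
    inside the fitted model from training data only.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    strat = None
    if stratify_labels is not None:
        _, counts = np.unique(np.asarray(stratify_labels, dtype=object), return_counts=True)
        if counts.min() >= 2:
            strat = stratify_labels
    idx_train, idx_test = train_test_split(
        np.arange(len(y)), train_size=train_fraction, random_state=seed, stratify=strat
    )
    if len(idx_test) < 2:
        raise ValueError("test partition smaller than 2 samples")
    model = _make_model(method, n_components)
    model.fit(X[idx_train], y[idx_train])
    pred_train = _predict(model, X[idx_train])
    pred_test = _predict(model, X[idx_test])
    ss = lambda a, b: float(np.sqrt(np.mean((a - b) ** 2)))  # noqa: E731
    r2 = lambda t, p: float(1.0 - ((t - p) ** 2).sum() / ((t - t.mean()) ** 2).sum())  # noqa: E731
    if method == "PLS":
        x_center = np.asarray(model._x_mean)
    else:
        x_center = np.asarray(model.named_steps["pca"].mean_)
    if rmsecv is None:
        rmsecv = np.array([np.nan] * n_components)
    return RegressionReport(
        method=method,
        target=target,
        n_components=n_components,
        rmsecv_curve=np.asarray(rmsecv, dtype=float),
        rmse=ss(y[idx_train], pred_train),
        rmsep=ss(y[idx_test], pred_test),
        r2=r2(y[idx_test], pred_test),
        r2_train=r2(y[idx_train], pred_train),
        split={
            "train_fraction": train_fraction,
            "seed": seed,
            "folds": folds,
            "n_train": int(len(idx_train)),
            "n_test": int(len(idx_test)),
        },
        x_center=x_center,
    )


def compare_methods(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int,
    folds: int = 10,
    seed: int = 0,
    target: str = "",
) -> MethodComparison:
    """PCR vs PLS: minimising component counts and RMSECV minima on the
    same target and fold assignment."""
    pcr = rmsecv_curve(X, y, "PCR", max_components, folds=folds, seed=seed)
    pls = rmsecv_curve(X, y, "PLS", max_components, folds=folds, seed=seed)
    return MethodComparison(
        target=target,
        pcr_components=select_components(pcr),
        pls_components=select_components(pls),
        pcr_rmsecv_min=float(pcr.min()),
        pls_rmsecv_min=float(pls.min()),
        pcr_curve=pcr,
        pls_curve=pls,
    )
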