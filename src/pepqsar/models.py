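"""QSAR model fitting and validation.

Four regression methods are fitted on the stepwise-screened, autoscaled
descriptors: multiple linear regression (MLR), partial least squares
(PLS), epsilon-support-vector regression (SVR, RBF kernel) and random
forest (RF). Models are trained on the standardized response and report
predictions back on the original activity scale (uM TE/uM).

Validation follows standard QSAR practice:

- ``R^2`` is the squared Pearson correlation between observed and
  calculated/predicted activities (the scatter-about-the-45-degree-line
  reading), not 1 - RSS/SS. The two coincide for OLS on training data.
- ``PRESS`` is the leave-one-out predicted residual sum of squares and
  ``Q^2 = 1 - PRESS / SS_total`` with SS_total taken about the full
  training mean; k-fold Q^2 replaces the LOO folds by a seeded k-way
  partition.
- ``SD = sqrt(RSS / (n - m - 1))`` and
  ``F = (R^2/m) / ((1 - R^2)/(n - m - 1))`` with ``m`` the number of
  screened variables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.svm import SVR

from .encoding import PeptideRecord, ScalingParams

#: Default SVR tuning grid (RBF kernel).
SVR_GRID = {"C": [0.1, 1.0, 10.0, 100.0], "gamma": [0.01, 0.1, 1.0], "epsilon": [0.01, 0.1]}

#: Default random-forest size.
RF_N_TREES = 500


def split_train_test(
    peptides: Sequence[PeptideRecord],
) -> tuple[list[PeptideRecord], list[PeptideRecord]]:
    """Descending-activity split: every third peptide (ranks 1, 4, 7, ...)
    goes to the test set, the rest to training.

    Peptides are sorted by activity descending, ties broken by sequence.
    Labels are written into ``subset_label``. With fewer than 3 records
    everything is training data (with a warning).
    """
    seqs = [p.sequence for p in peptides]
    if len(set(seqs)) != len(seqs):
        raise ValueError("duplicate sequences in peptide set")
    if any(p.activity is None for p in peptides):
        raise ValueError("all peptides need an activity for splitting")
    ordered = sorted(peptides, key=lambda p: (-p.activity, p.sequence))
    if len(ordered) < 3:
        warnings.warn("fewer than 3 peptides: all assigned to training")
        for p in ordered:
            p.subset_label = "train"
        return list(ordered), []
    train, test = [], []
    for rank, p in enumerate(ordered, start=1):
        if rank % 3 == 1:
            p.subset_label = "test"
            test.append(p)
        else:
            p.subset_label = "train"
            train.append(p)
    return train, test


@dataclass
class ModelMetrics:
    """The validation metric bundle reported for every fitted model."""

    r2_train: float
    sd: float
    f_stat: float
    press: float
    q2_loo: float
    q2_kfold: dict[int, float] = field(default_factory=dict)
    r2_test: float | None = None
    ss_total: float | None = None
    n_train: int | None = None
    n_variables: int | None = None

    def to_dict(self) -> dict:
        return {
            "r2_train": self.r2_train,
            "sd": self.sd,
            "f": self.f_stat,
            "press": self.press,
            "q2_loo": self.q2_loo,
            "q2_kfold": {str(k): v for k, v in self.q2_kfold.items()},
            "r2_test": self.r2_test,
            "ss_total": self.ss_total,
            "n_train": self.n_train,
            "n_variables": self.n_variables,
        }


@dataclass
class FittedModel:
    """A fitted QSAR model plus everything needed to reuse it.

    ``coefficients`` (per-variable, on the standardized scale — i.e. the
    normalized regression coefficients) are present for the linear
    methods only. ``predict`` always returns activities on the original
    scale via the stored response scaling.
    """

    method: str  # "MLR" | "PLS" | "SVR" | "RF"
    variables: list[str]
    scaling: ScalingParams
    coefficients: np.ndarray | None = None
    hyperparameters: dict = field(default_factory=dict)
    seed: int | None = None
    metrics: ModelMetrics | None = None
    _estimator: object | None = field(default=None, repr=False)

    def predict_scaled(self, Z: pd.DataFrame) -> np.ndarray:
        """Predict the standardized response from scaled descriptors."""
        X = Z[self.variables].to_numpy(dtype=float)
        if self.method in ("MLR",):
            return X @ self.coefficients
        pred = self._estimator.predict(X)
        return np.asarray(pred, dtype=float).ravel()

    def predict(self, Z: pd.DataFrame) -> np.ndarray:
        """Predict activity on the original (uM TE/uM) scale."""
        return self.scaling.unscale_y(self.predict_scaled(Z))

    def cv_fitter(self) -> "Fitter":
        """A refitting callable with hyperparameters frozen (no re-tuning),
        for use inside cross-validation loops."""
        method = self.method
        if method == "MLR":
            return lambda Z, y: fit_mlr(Z, y, self.scaling, variables=self.variables)
        if method == "PLS":
            k = self.hyperparameters["n_components"]
            return lambda Z, y: fit_pls(
                Z, y, self.scaling, n_components=k, variables=self.variables
            )
        est = self._estimator

        def refit(Z: pd.DataFrame, y: np.ndarray) -> FittedModel:
            new = clone(est)
            new.fit(Z[self.variables].to_numpy(dtype=float), y)
            return FittedModel(
                method=method,
                variables=self.variables,
                scaling=self.scaling,
                hyperparameters=dict(self.hyperparameters),
                seed=self.seed,
                _estimator=new,
            )

        return refit

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "variables": self.variables,
            "coefficients": None
            if self.coefficients is None
            else [float(c) for c in self.coefficients],
            "hyperparameters": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.hyperparameters.items()
            },
            "seed": self.seed,
            "scaling": {
                "mean": self.scaling.mean.to_dict(),
                "sd": self.scaling.sd.to_dict(),
                "y_mean": self.scaling.y_mean,
                "y_sd": self.scaling.y_sd,
            },
            "metrics": None if self.metrics is None else self.metrics.to_dict(),
        }


Fitter = Callable[[pd.DataFrame, np.ndarray], FittedModel]


def _design(Z: pd.DataFrame, variables: Sequence[str] | None) -> tuple[list[str], np.ndarray]:
    cols = list(variables) if variables is not None else list(Z.columns)
    return cols, Z[cols].to_numpy(dtype=float)


def fit_mlr(
    Z: pd.DataFrame,
    y_scaled: Sequence[float],
    scaling: ScalingParams,
    variables: Sequence[str] | None = None,
) -> FittedModel:
    """Ordinary least squares on standardized variables (no intercept;
    it is zero by construction after centering)."""
    cols, X = _design(Z, variables)
    yv = np.asarray(y_scaled, dtype=float)
    if X.shape[0] <= X.shape[1] + 1:
        raise ValueError("MLR needs rows > variables + 1")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        redundant = [
            cols[j]
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise ValueError(f"singular design; collinear variables: {redundant}")
    coef, _, _, _ = np.linalg.lstsq(X, yv, rcond=None)
    return FittedModel(method="MLR", variables=cols, scaling=scaling, coefficients=coef)


def fit_pls(
    Z: pd.DataFrame,
    y_scaled: Sequence[float],
    scaling: ScalingParams,
    n_components: int | None = None,
    variables: Sequence[str] | None = None,
) -> FittedModel:
    """PLS regression; when ``n_components`` is omitted it is chosen by
    maximizing leave-one-out Q^2 over 1..n_variables."""
    cols, X = _design(Z, variables)
    yv = np.asarray(y_scaled, dtype=float)
    m = len(cols)
    if n_components is None:
        best = None
        for k in range(1, min(m, int(np.linalg.matrix_rank(X))) + 1):
            press = 0.0
            for i in range(len(yv)):
                keep = np.arange(len(yv)) != i
                pls = PLSRegression(n_components=k, scale=False)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    pls.fit(X[keep], yv[keep])
                press += float(yv[i] - pls.predict(X[i : i + 1]).ravel()[0]) ** 2
            q2 = 1.0 - press / float(((yv - yv.mean()) ** 2).sum())
            if best is None or q2 > best[0]:
                best = (q2, k)
        n_components = best[1]
    if not 1 <= n_components <= m:
        raise ValueError(f"n_components must be in 1..{m}, got {n_components}")
    # components beyond the design rank carry no signal and are numerically
    # unstable; predictions are unchanged by capping
    effective = min(int(n_components), int(np.linalg.matrix_rank(X)))
    pls = PLSRegression(n_components=effective, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls.fit(X, yv)
    coef = np.asarray(pls.coef_, dtype=float).reshape(-1)
    return FittedModel(
        method="PLS",
        variables=cols,
        scaling=scaling,
        coefficients=coef,
        hyperparameters={"n_components": int(n_components), "effective_components": effective},
        _estimator=pls,
    )


def fit_svr(
    Z: pd.DataFrame,
    y_scaled: Sequence[float],
    scaling: ScalingParams,
    seed: int = 0,
    param_grid: dict | None = None,
    variables: Sequence[str] | None = None,
) -> FittedModel:
    """RBF-kernel epsilon-SVR; (C, gamma, epsilon) chosen by seeded 5-fold
    grid search on the training data, then refitted on all rows."""
    cols, X = _design(Z, variables)
    yv = np.asarray(y_scaled, dtype=float)
    if np.std(yv) == 0:
        raise ValueError("degenerate response: zero variance")
    grid = param_grid or SVR_GRID
    n_splits = min(5, len(yv))
    search = GridSearchCV(
        SVR(kernel="rbf"),
        grid,
        cv=KFold(n_splits=n_splits, shuffle=True, random_state=seed),
        scoring="r2",
    )
    search.fit(X, yv)
    est = search.best_estimator_
    return FittedModel(
        method="SVR",
        variables=cols,
        scaling=scaling,
        hyperparameters={"kernel": "rbf", **search.best_params_},
        seed=seed,
        _estimator=est,
    )


def fit_rf(
    Z: pd.DataFrame,
    y_scaled: Sequence[float],
    scaling: ScalingParams,
    seed: int = 0,
    n_trees: int = RF_N_TREES,
    variables: Sequence[str] | None = None,
) -> FittedModel:
    """Regression random forest with a fixed tree count and seed."""
    cols, X = _design(Z, variables)
    yv = np.asarray(y_scaled, dtype=float)
    if np.std(yv) == 0:
        raise ValueError("degenerate response: zero variance")
    rf = RandomForestRegressor(n_estimators=n_trees, random_state=seed)
    rf.fit(X, yv)
    return FittedModel(
        method="RF",
        variables=cols,
        scaling=scaling,
        hyperparameters={"n_trees": n_trees},
        seed=seed,
        _estimator=rf,
    )


def r2_pearson(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Squared Pearson correlation between observed and predicted values."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.std() == 0 or pred.std() == 0:
        raise ValueError("zero variance in observed or predicted values")
    return float(np.corrcoef(obs, pred)[0, 1] ** 2)


def f_statistic(r2: float, n: int, m: int) -> float:
    """Regression F statistic from R^2 with m variables on n samples:
    F = (R^2/m) / ((1-R^2)/(n-m-1))."""
    if n - m - 1 <= 0:
        raise ValueError("n - m - 1 must be positive")
    if r2 >= 1.0:
        return math.inf
    return (r2 / m) / ((1.0 - r2) / (n - m - 1))


def loo_q2(
    fitter: Fitter,
    Z: pd.DataFrame,
    y: Sequence[float],
    scaling: ScalingParams,
) -> tuple[float, float]:
    """Leave-one-out Q^2 and PRESS (on the original activity scale).

    For each row the model is refitted on the remaining rows (with the
    scaling and hyperparameters of the parent fit) and the held-out row
    predicted; ``PRESS = sum (y_i - yhat_(-i))^2`` and
    ``Q^2 = 1 - PRESS / sum (y_i - ybar)^2`` with ybar the full mean.
    """
    yv = np.asarray(y, dtype=float)
    n = len(yv)
    if n < 3:
        raise ValueError("LOO needs at least 3 rows")
    ss_total = float(((yv - yv.mean()) ** 2).sum())
    if ss_total <= 0:
        raise ValueError("zero total sum of squares")
    y_scaled = scaling.scale_y(yv)
    press = 0.0
    for i in range(n):
        keep = np.arange(n) != i
        model = fitter(Z.iloc[keep], y_scaled[keep])
        pred = model.predict(Z.iloc[[i]])[0]
        press += float(yv[i] - pred) ** 2
    return 1.0 - press / ss_total, press


def kfold_q2(
    fitter: Fitter,
    Z: pd.DataFrame,
    y: Sequence[float],
    scaling: ScalingParams,
    k: int,
    seed: int = 0,
    shuffle: bool = True,
) -> float:
    """k-fold Q^2: rows shuffled with ``seed`` and split into k near-equal
    folds; Q^2 = 1 - sum of held-out squared errors / SS_total."""
    yv = np.asarray(y, dtype=float)
    n = len(yv)
    if not 2 <= k <= n:
        raise ValueError(f"k must be in 2..{n}")
    ss_total = float(((yv - yv.mean()) ** 2).sum())
    if ss_total <= 0:
        raise ValueError("zero total sum of squares")
    indices = np.arange(n)
    if shuffle:
        indices = np.random.default_rng(seed).permutation(n)
    y_scaled = scaling.scale_y(yv)
    press = 0.0
    for fold in np.array_split(indices, k):
        keep = np.setdiff1d(np.arange(n), fold)
        model = fitter(Z.iloc[keep], y_scaled[keep])
        pred = model.predict(Z.iloc[fold])
        press += float(((yv[fold] - pred) ** 2).sum())
    return 1.0 - press / ss_total


def summarize(
    model: FittedModel,
    Z_train: pd.DataFrame,
    y_train: Sequence[float],
    Z_test: pd.DataFrame | None = None,
    y_test: Sequence[float] | None = None,
    k_values: Sequence[int] = (4, 6, 10),
    seed: int = 0,
) -> ModelMetrics:
    """Compute the full metric bundle for a fitted model and attach it."""
    y_tr = np.asarray(y_train, dtype=float)
    fitted = model.predict(Z_train)
    n, m = len(y_tr), len(model.variables)
    r2_train = r2_pearson(y_tr, fitted)
    rss = float(((y_tr - fitted) ** 2).sum())
    sd = math.sqrt(rss / (n - m - 1)) if n - m - 1 > 0 else math.inf
    f_stat = f_statistic(r2_train, n, m)
    fitter = model.cv_fitter()
    q2, press = loo_q2(fitter, Z_train, y_tr, model.scaling)
    q2_kfold = {
        int(k): kfold_q2(fitter, Z_train, y_tr, model.scaling, int(k), seed=seed)
        for k in k_values
    }
    r2_test = None
    if Z_test is not None and y_test is not None and len(Z_test) > 0:
        r2_test = r2_pearson(y_test, model.predict(Z_test))
    metrics = ModelMetrics(
        r2_train=r2_train,
        sd=sd,
        f_stat=f_stat,
        press=press,
        q2_loo=q2,
        q2_kfold=q2_kfold,
        r2_test=r2_test,
        ss_total=float(((y_tr - y_tr.mean()) ** 2).sum()),
        n_train=n,
        n_variables=m,
    )
    model.metrics = metrics
    return metrics
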