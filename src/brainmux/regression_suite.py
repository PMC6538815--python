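"""Age regression: deep feedforward network, four classical baselines, and
repeated k-fold cross-validation with optional grid search.

The deep model is a feedforward net with four hidden layers of 200, 100, 50,
and 20 tanh units by default, trained to minimize squared error. Baselines
are Ridge, Lasso, Random Forest, and epsilon-SVR. Features are z-scored with
training-fold statistics before every fit (tanh units and penalized
regressions need comparable scales), and when features are built from a
multiplex, the across-layer reference is fitted on training folds only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence, Union

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Lasso, Ridge
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

__all__ = [
    "DnnConfig",
    "BaselineConfig",
    "CVResult",
    "DnnModel",
    "fit_dnn",
    "fit_baseline",
    "grid_search",
    "repeated_kfold",
    "ArrayFeatureSource",
]

_MOD = 2**31


def _derive_seed(seed: int, step: int) -> int:
    """Deterministic child seed; identity at step 0 so nesting composes."""
    return (seed + 1000003 * step) % _MOD


@dataclass
class DnnConfig:
    """Deep net configuration. Defaults are the reference architecture:
    four hidden layers of 200/100/50/20 tanh units."""

    hidden_sizes: tuple[int, ...] = (200, 100, 50, 20)
    activation: str = "tanh"
    epochs: int = 400
    learning_rate: float = 1e-3
    l1: float = 0.0
    l2: float = 1e-4
    seed: int = 0
    early_stopping: bool = True
    validation_fraction: float = 0.1

    def __post_init__(self) -> None:
        if len(self.hidden_sizes) < 2:
            raise ValueError("need at least two hidden layers (importance uses both)")
        if self.activation not in ("tanh", "relu"):
            raise ValueError(f"unsupported activation {self.activation!r}")
        if self.l1 != 0.0:
            raise ValueError("L1 penalty is not supported by the MLP backend; use l2")


@dataclass
class BaselineConfig:
    """One classical baseline: ridge | lasso | rf | svm."""

    kind: str
    lam: float = 1.0  # ridge/lasso penalty weight
    n_trees: int = 100  # rf
    max_features: float = 1.0 / 3.0  # rf features per split (fraction)
    epsilon: float = 0.1  # svm tube width
    cost: float = 1.0  # svm regularization C
    kernel: str = "rbf"  # svm kernel
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("ridge", "lasso", "rf", "svm"):
            raise ValueError(f"unknown baseline kind {self.kind!r}")
        if self.lam < 0:
            raise ValueError("penalty must be >= 0")
        if self.n_trees < 1:
            raise ValueError("need at least one tree")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


ModelConfig = Union[DnnConfig, BaselineConfig]


class DnnModel:
    """Feedforward regressor with internal target scaling.

    Targets are z-scored at fit time (tanh output paths train poorly on
    raw year scales) and predictions are mapped back. Per-layer weight
    matrices are exposed for weight-path feature importance.
    """

    def __init__(self, cfg: DnnConfig) -> None:
        self.cfg = cfg
        self._net = None
        self._y_mean = 0.0
        self._y_scale = 1.0
        self._constant_target = False

    def _make_net(self, early_stopping: bool) -> MLPRegressor:
        cfg = self.cfg
        return MLPRegressor(
            hidden_layer_sizes=cfg.hidden_sizes,
            activation=cfg.activation,
            solver="adam",
            alpha=cfg.l2,
            learning_rate_init=cfg.learning_rate,
            max_iter=cfg.epochs,
            early_stopping=early_stopping,
            validation_fraction=cfg.validation_fraction,
            n_iter_no_change=25,
            tol=1e-6,
            random_state=cfg.seed,
        )

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        """(n_inputs, *hidden, 1) — available after fit."""
        return (self._net.coefs_[0].shape[0], *self.cfg.hidden_sizes, 1)

    @property
    def coefs(self) -> list[np.ndarray]:
        """Weight matrices per layer; coefs[0] maps inputs to hidden 1."""
        return self._net.coefs_

    def fit(self, X: np.ndarray, y: np.ndarray) -> "DnnModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in training data")
        self._y_mean = float(y.mean())
        sd = float(y.std())
        self._y_scale = sd if sd > 0 else 1.0
        # a constant target has nothing to learn: the mean is the exact
        # least-squares solution, and the validation R^2 driving early
        # stopping is undefined; the net is still fitted so that layer
        # weights stay retrievable
        self._constant_target = sd == 0
        self._net = self._make_net(self.cfg.early_stopping and not self._constant_target)
        self._net.fit(X, (y - self._y_mean) / self._y_scale)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self._constant_target:
            return np.full(X.shape[0], self._y_mean)
        return self._net.predict(X) * self._y_scale + self._y_mean


def fit_dnn(X: np.ndarray, y: np.ndarray, cfg: DnnConfig | None = None) -> DnnModel:
    """Train the deep regressor; weights of every layer stay retrievable."""
    return DnnModel(cfg or DnnConfig()).fit(X, y)


def fit_baseline(X: np.ndarray, y: np.ndarray, cfg: BaselineConfig):
    """Train one classical baseline; all expose predict()."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in training data")
    if cfg.kind == "ridge":
        model = Ridge(alpha=cfg.lam)
    elif cfg.kind == "lasso":
        model = Lasso(alpha=cfg.lam, max_iter=50000)
    elif cfg.kind == "rf":
        model = RandomForestRegressor(
            n_estimators=cfg.n_trees,
            max_features=cfg.max_features,
            random_state=cfg.seed,
        )
    else:  # svm
        model = SVR(kernel=cfg.kernel, C=cfg.cost, epsilon=cfg.epsilon)
    return model.fit(X, y)


def _fit_any(X: np.ndarray, y: np.ndarray, cfg: ModelConfig, seed: int):
    cfg = replace(cfg, seed=seed)
    if isinstance(cfg, DnnConfig):
        return fit_dnn(X, y, cfg)
    return fit_baseline(X, y, cfg)


class ArrayFeatureSource:
    """Fixed feature matrix wrapped in the fold-wise feature interface."""

    def __init__(self, X: np.ndarray, y: np.ndarray) -> None:
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y disagree on sample count")

    def __len__(self) -> int:
        return self.X.shape[0]

    def make(self, train_idx, test_idx):
        return self.X[train_idx], self.X[test_idx]


@dataclass
class CVResult:
    """Out-of-fold predictions and per-repetition metrics."""

    y: np.ndarray  # (S,)
    predictions: np.ndarray  # (R, S) out-of-fold
    fold_assignments: np.ndarray  # (R, S) integer fold per subject
    metrics: pd.DataFrame  # per repetition: mae, rmse, rho
    model_kind: str
    config: ModelConfig = None
    seed: int = 0

    @property
    def pooled_predictions(self) -> np.ndarray:
        """Mean out-of-fold prediction per subject across repetitions."""
        return self.predictions.mean(axis=0)

    def summary(self) -> pd.DataFrame:
        """mean / SD / SE of each metric across repetitions."""
        m = self.metrics[["mae", "rmse", "rho"]]
        return pd.DataFrame(
            {"mean": m.mean(), "sd": m.std(ddof=1), "se": m.sem()}
        )

    def to_frame(self) -> pd.DataFrame:
        """Long table: (subject, repetition, fold, y, yhat)."""
        R, S = self.predictions.shape
        rep, subj = np.meshgrid(np.arange(R), np.arange(S), indexing="ij")
        return pd.DataFrame(
            {
                "subject": subj.ravel(),
                "repetition": rep.ravel(),
                "fold": self.fold_assignments.ravel(),
                "y": np.tile(self.y, R),
                "yhat": self.predictions.ravel(),
            }
        )


def _pooled_metrics(y: np.ndarray, yhat: np.ndarray) -> dict[str, float]:
    err = y - yhat
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    if np.std(y) == 0 or np.std(yhat) == 0:
        rho = float("nan")
    else:
        rho = float(np.corrcoef(y, yhat)[0, 1])
    return {"mae": mae, "rmse": rmse, "rho": rho}


def repeated_kfold(
    data,
    y: np.ndarray | None = None,
    config: ModelConfig | None = None,
    k: int = 10,
    repetitions: int = 5,
    seed: int = 0,
) -> CVResult:
    """Repeated k-fold cross-validation with out-of-fold predictions.

    ``data`` is a feature source (``ArrayFeatureSource``,
    ``MultiplexFeatureSource``) or a plain S x M array together with ``y``.
    Each repetition reshuffles subjects with a derived seed and predicts
    every subject exactly once from a model whose training folds excluded
    it. Feature standardization (and, for multiplex sources, the across-layer
    reference) is fitted on training folds only.
    """
    if isinstance(data, np.ndarray):
        if y is None:
            raise ValueError("y required with an array input")
        source = ArrayFeatureSource(data, y)
    else:
        source = data
    yv = np.asarray(source.y, dtype=float)
    S = len(source)
    if k < 2:
        raise ValueError("k must be >= 2")
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    if S < k:
        raise ValueError(f"sample size {S} smaller than k={k}")
    config = config or DnnConfig()
    kind = "dnn" if isinstance(config, DnnConfig) else config.kind

    preds = np.empty((repetitions, S))
    folds = np.empty((repetitions, S), dtype=int)
    rows = []
    for r in range(repetitions):
        rep_seed = _derive_seed(seed, r)
        splitter = KFold(n_splits=k, shuffle=True, random_state=rep_seed)
        for f, (train_idx, test_idx) in enumerate(splitter.split(np.arange(S))):
            X_tr, X_te = source.make(train_idx, test_idx)
            scaler = StandardScaler().fit(X_tr)
            model = _fit_any(
                scaler.transform(X_tr),
                yv[train_idx],
                config,
                seed=(rep_seed + f + 1) % _MOD,
            )
            preds[r, test_idx] = model.predict(scaler.transform(X_te))
            folds[r, test_idx] = f
        rows.append({"repetition": r, **_pooled_metrics(yv, preds[r])})
    return CVResult(
        y=yv,
        predictions=preds,
        fold_assignments=folds,
        metrics=pd.DataFrame(rows),
        model_kind=kind,
        config=config,
        seed=seed,
    )


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    base_config: ModelConfig,
    grids: dict[str, Sequence],
    k: int = 5,
    seed: int = 0,
) -> tuple[ModelConfig, pd.DataFrame]:
    """Exhaustive search over a hyperparameter grid by cross-validated MAE.

    Each grid point is scored with a single seeded k-fold pass; the argmin
    configuration and the full score table are returned. Deterministic
    given the seed (ties go to the first grid point in iteration order).
    """
    if not grids or any(len(v) == 0 for v in grids.values()):
        raise ValueError("empty grid")
    names = list(grids)
    rows = []
    best_cfg, best_mae = None, np.inf
    for values in itertools.product(*(grids[n] for n in names)):
        cfg = replace(base_config, **dict(zip(names, values)))
        res = repeated_kfold(X, y, cfg, k=k, repetitions=1, seed=seed)
        mae = float(res.metrics["mae"].iloc[0])
        rows.append({**dict(zip(names, values)), "cv_mae": mae})
        if mae < best_mae:
            best_cfg, best_mae = cfg, mae
    return best_cfg, pd.DataFrame(rows)
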