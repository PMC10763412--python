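"""Feed-forward abundance regression.

The estimator regresses relative reporter abundance on the 15 UTR features
with a multi-layer perceptron (default 3 hidden layers of 300 rectified-
linear units, linear output, squared-error loss, adam).  Abundance is a
multiplicative phenotype spanning orders of magnitude, so the network is
fitted to log2(y); ``predict`` returns values back on the original scale
and ``predict_log2`` exposes the modelling scale.  Coefficients of
determination reported by the evaluation helpers are computed on the log2
scale for the same reason.

Feature standardisation (per-feature z-score) is fitted strictly on the
training rows of each split; the fitted scaler travels with the estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .features import FEATURE_NAMES


@dataclass
class Dataset:
    """Feature matrix + abundance + row labels."""

    X: pd.DataFrame
    y: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if len(self.X) != len(self.y) or len(self.X) != len(self.ids):
            raise ValueError("X, y and ids must agree in length")
        if self.X.isna().any().any() or np.isnan(self.y).any():
            raise ValueError("dataset contains missing values")
        if (self.y <= 0).any():
            raise ValueError("abundance must be positive")

    @property
    def n(self) -> int:
        return len(self.y)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Dataset":
        missing = [c for c in ("id", "abundance", *FEATURE_NAMES) if c not in df]
        if missing:
            raise ValueError(f"dataset table lacks columns {missing}")
        return cls(
            X=df[list(FEATURE_NAMES)].astype(float).reset_index(drop=True),
            y=df["abundance"].to_numpy(float),
            ids=df["id"].astype(str).tolist(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        out = self.X.copy()
        out.insert(0, "id", self.ids)
        out["abundance"] = self.y
        return out


@dataclass(frozen=True)
class SplitSpec:
    train: np.ndarray
    test: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if np.intersect1d(self.train, self.test).size:
            raise ValueError("train/test overlap")


def make_split(n: int, test_fraction: float = 0.2, seed: int = 0) -> SplitSpec:
    """Seeded disjoint, exhaustive train/test split.

    The test size is ``round(test_fraction * n)`` (at least 1), so 241
    rows at 0.2 give the 193/48 partition used throughout.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    if n < 10:
        raise ValueError("need at least 10 rows to split")
    n_test = max(1, round(test_fraction * n))
    perm = np.random.default_rng(seed).permutation(n)
    return SplitSpec(train=np.sort(perm[n_test:]), test=np.sort(perm[:n_test]), seed=seed)


def r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.size != y_hat.size or y.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("y is constant: R^2 undefined")
    return 1.0 - float(np.sum((y - y_hat) ** 2)) / ss_tot


class AbundanceRegressor(RegressorMixin, BaseEstimator):
    """MLP abundance regressor with built-in scaling and log2 target.

    Parameters
    ----------
    hidden_layer_sizes : tuple of int
        Hidden architecture; default three layers of 300 relu units.
    max_iter, n_iter_no_change, validation_fraction, tol, learning_rate_init :
        Training schedule (adam, squared loss, early stopping on a 10%
        validation carve-out of the training rows with patience 50).
    batch_size : "full" or int
        "full" trains on the whole (post-carve-out) training set per step.
    log_target : bool
        Fit log2(y) (default).  ``predict`` always returns the original
        scale; ``predict_log2`` the modelling scale.
    random_state : int or None
        Seeds weight initialisation and the validation carve-out; two fits
        with the same seed and data produce identical predictions.
    """

    def __init__(
        self,
        hidden_layer_sizes: tuple[int, ...] = (300, 300, 300),
        max_iter: int = 2000,
        n_iter_no_change: int = 50,
        validation_fraction: float = 0.1,
        tol: float = 1e-4,
        learning_rate_init: float = 1e-3,
        batch_size: str | int = "full",
        log_target: bool = True,
        random_state: int | None = None,
    ) -> None:
        self.hidden_layer_sizes = hidden_layer_sizes
        self.max_iter = max_iter
        self.n_iter_no_change = n_iter_no_change
        self.validation_fraction = validation_fraction
        self.tol = tol
        self.learning_rate_init = learning_rate_init
        self.batch_size = batch_size
        self.log_target = log_target
        self.random_state = random_state

    def _validate_X(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if hasattr(self, "feature_names_in_") and list(X.columns) != list(
                self.feature_names_in_
            ):
                raise ValueError("feature columns do not match the fitted order")
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if hasattr(self, "n_features_in_") and X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} columns, estimator was fitted with "
                f"{self.n_features_in_}"
            )
        return X

    def fit(self, X, y) -> "AbundanceRegressor":
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        X = self._validate_X(X)
        y = np.asarray(y, dtype=float)
        if y.ndim != 1 or y.size != X.shape[0]:
            raise ValueError("y must be 1-d and match X rows")
        if self.log_target and (y <= 0).any():
            raise ValueError("log-target fitting requires positive abundance")
        self.n_features_in_ = X.shape[1]
        target = np.log2(y) if self.log_target else y

        self.scaler_ = StandardScaler().fit(X)
        self._scaler_fit_rows = X.shape[0]  # leakage guard: rows the scaler saw
        if self.batch_size == "full":
            # size of the training portion left after the validation carve-out
            batch = max(1, X.shape[0] - int(np.ceil(self.validation_fraction * X.shape[0])))
        else:
            batch = self.batch_size
        self.mlp_ = MLPRegressor(
            hidden_layer_sizes=self.hidden_layer_sizes,
            activation="relu",
            solver="adam",
            max_iter=self.max_iter,
            early_stopping=True,
            validation_fraction=self.validation_fraction,
            n_iter_no_change=self.n_iter_no_change,
            tol=self.tol,
            learning_rate_init=self.learning_rate_init,
            batch_size=batch,
            random_state=self.random_state,
        )
        self.mlp_.fit(self.scaler_.transform(X), target)
        if not np.isfinite(self.mlp_.loss_):
            raise RuntimeError(
                f"training diverged: final loss {self.mlp_.loss_!r}, "
                f"lr={self.learning_rate_init}"
            )
        self.training_log_ = {
            "loss_curve": list(self.mlp_.loss_curve_),
            "validation_scores": list(getattr(self.mlp_, "validation_scores_", [])),
            "n_iter": int(self.mlp_.n_iter_),
            "seed": self.random_state,
        }
        return self

    def predict_log2(self, X) -> np.ndarray:
        check_is_fitted(self, "mlp_")
        X = self._validate_X(X)
        return self.mlp_.predict(self.scaler_.transform(X))

    def predict(self, X) -> np.ndarray:
        pred = self.predict_log2(X)
        return np.power(2.0, pred) if self.log_target else pred

    def score(self, X, y) -> float:
        """R^2 on the modelling scale (log2 when log_target is set)."""
        y = np.asarray(y, dtype=float)
        if self.log_target:
            return r_squared(np.log2(y), self.predict_log2(X))
        return r_squared(y, self.predict(X))


def _n_params(layers: int, units: int, n_features: int = len(FEATURE_NAMES)) -> int:
    sizes = [n_features] + [units] * layers + [1]
    return sum((a + 1) * b for a, b in zip(sizes[:-1], sizes[1:]))


def cross_validate(
    X,
    y,
    grid: dict | None = None,
    k: int = 5,
    seed: int = 0,
    **estimator_kwargs,
) -> dict:
    """k-fold CV over a (layers x units) grid on the training rows.

    Returns the grid point with the highest mean validation R^2; ties are
    broken toward the smaller network (fewer parameters).  Fold sizes
    differ by at most 1 and partition the rows.
    """
    grid = grid or {"n_layers": [1, 2, 3], "units_per_layer": [50, 100, 300]}
    if not grid["n_layers"] or not grid["units_per_layer"]:
        raise ValueError("empty hyperparameter grid")
    X = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    y = np.asarray(y, dtype=float)
    if len(y) < 2 * k:
        raise ValueError("folds would contain fewer than 2 rows")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    results = []
    for layers in grid["n_layers"]:
        for units in grid["units_per_layer"]:
            scores = []
            for fold_i, (tr, va) in enumerate(kf.split(X)):
                est = AbundanceRegressor(
                    hidden_layer_sizes=(units,) * layers,
                    random_state=seed * 1000 + fold_i,
                    **estimator_kwargs,
                )
                est.fit(X[tr], y[tr])
                scores.append(est.score(X[va], y[va]))
            results.append(
                {
                    "n_layers": layers,
                    "units_per_layer": units,
                    "mean_val_r2": float(np.mean(scores)),
                    "fold_r2": scores,
                    "n_params": _n_params(layers, units, X.shape[1]),
                }
            )
    best = max(results, key=lambda r: (r["mean_val_r2"], -r["n_params"]))
    return {"best": best, "table": results}


def train_mlp(
    dataset: Dataset,
    split: SplitSpec,
    hidden_layer_sizes: tuple[int, ...] = (300, 300, 300),
    seed: int = 0,
    **kwargs,
) -> AbundanceRegressor:
    """Fit the regressor on the training rows of a split.

    The returned estimator carries its split and seed (``split_``,
    ``seed_``) so downstream attribution and optimisation stages can reuse
    them.
    """
    est = AbundanceRegressor(
        hidden_layer_sizes=hidden_layer_sizes, random_state=seed, **kwargs
    )
    est.fit(dataset.X.iloc[split.train], dataset.y[split.train])
    est.split_ = split
    est.seed_ = seed
    return est


@dataclass
class EvalReport:
    per_split: list[dict] = field(default_factory=list)

    @property
    def mean_test_r2(self) -> float:
        return float(np.mean([s["r2_test"] for s in self.per_split]))

    @property
    def mean_train_r2(self) -> float:
        return float(np.mean([s["r2_train"] for s in self.per_split]))


def repeated_evaluation(
    dataset: Dataset,
    n_splits: int = 5,
    seeds: list[int] | None = None,
    test_fraction: float = 0.2,
    hidden_layer_sizes: tuple[int, ...] = (300, 300, 300),
    drop_features: tuple[str, ...] = (),
    **kwargs,
) -> EvalReport:
    """Train/test R^2 over repeated seeded splits (mean + per split).

    ``drop_features`` removes columns before training, with the *same*
    splits as the full run for any given seed list, enabling paired
    ablation comparisons.
    """
    seeds = list(range(n_splits)) if seeds is None else list(seeds)
    unknown = set(drop_features) - set(dataset.X.columns)
    if unknown:
        raise ValueError(f"unknown features {sorted(unknown)}")
    keep = [c for c in dataset.X.columns if c not in drop_features]
    if not keep:
        raise ValueError("cannot drop every feature")
    X = dataset.X[keep]
    report = EvalReport()
    for s in seeds:
        split = make_split(dataset.n, test_fraction=test_fraction, seed=s)
        est = AbundanceRegressor(
            hidden_layer_sizes=hidden_layer_sizes, random_state=s, **kwargs
        )
        est.fit(X.iloc[split.train], dataset.y[split.train])
        report.per_split.append(
            {
                "seed": s,
                "n_train": int(split.train.size),
                "n_test": int(split.test.size),
                "r2_train": est.score(X.iloc[split.train], dataset.y[split.train]),
                "r2_test": est.score(X.iloc[split.test], dataset.y[split.test]),
            }
        )
    return report


def save_bundle(est: AbundanceRegressor, directory) -> None:
    """Persist a fitted estimator as portable JSON text weights.

    Layout: ``bundle.json`` holding the constructor params, the scaler
    statistics, the network weights (nested lists, layer by layer) and the
    split/seed provenance when present.
    """
    import json
    from pathlib import Path

    check_is_fitted(est, "mlp_")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    payload = {
        "params": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in est.get_params().items()
        },
        "scaler": {
            "mean": est.scaler_.mean_.tolist(),
            "scale": est.scaler_.scale_.tolist(),
        },
        "weights": [w.tolist() for w in est.mlp_.coefs_],
        "biases": [b.tolist() for b in est.mlp_.intercepts_],
        "n_features_in": int(est.n_features_in_),
        "feature_names": (
            list(est.feature_names_in_) if hasattr(est, "feature_names_in_") else None
        ),
        "training_log": est.training_log_,
        "split": (
            {
                "train": est.split_.train.tolist(),
                "test": est.split_.test.tolist(),
                "seed": est.split_.seed,
            }
            if hasattr(est, "split_")
            else None
        ),
    }
    with open(directory / "bundle.json", "w") as fh:
        json.dump(payload, fh)
        fh.write("\n")


def load_bundle(directory) -> AbundanceRegressor:
    """Reconstruct a fitted estimator from :func:`save_bundle` output."""
    import json
    from pathlib import Path

    with open(Path(directory) / "bundle.json") as fh:
        payload = json.load(fh)
    params = dict(payload["params"])
    params["hidden_layer_sizes"] = tuple(params["hidden_layer_sizes"])
    est = AbundanceRegressor(**params)
    est.n_features_in_ = payload["n_features_in"]
    if payload["feature_names"]:
        est.feature_names_in_ = np.asarray(payload["feature_names"], dtype=object)
    est.scaler_ = StandardScaler()
    est.scaler_.mean_ = np.asarray(payload["scaler"]["mean"])
    est.scaler_.scale_ = np.asarray(payload["scaler"]["scale"])
    est.scaler_.var_ = est.scaler_.scale_ ** 2
    est.scaler_.n_features_in_ = est.n_features_in_
    # rebuild the network shell and hand it the stored weights
    mlp = MLPRegressor(hidden_layer_sizes=params["hidden_layer_sizes"])
    mlp.coefs_ = [np.asarray(w) for w in payload["weights"]]
    mlp.intercepts_ = [np.asarray(b) for b in payload["biases"]]
    mlp.n_layers_ = len(mlp.coefs_) + 1
    mlp.n_outputs_ = 1
    mlp.out_activation_ = "identity"
    mlp.activation = "relu"
    mlp.n_features_in_ = est.n_features_in_
    est.mlp_ = mlp
    est.training_log_ = payload["training_log"]
    if payload["split"]:
        est.split_ = SplitSpec(
            train=np.asarray(payload["split"]["train"]),
            test=np.asarray(payload["split"]["test"]),
            seed=payload["split"]["seed"],
        )
    return est


def ablation_evaluation(
    dataset: Dataset,
    dropped: tuple[str, ...] = ("utr_length", "polya_length", "polya_position"),
    n_splits: int = 5,
    seeds: list[int] | None = None,
    **kwargs,
) -> EvalReport:
    """Repeated evaluation with features removed (paired splits/seeds)."""
    return repeated_evaluation(
        dataset, n_splits=n_splits, seeds=seeds, drop_features=tuple(dropped), **kwargs
    )
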