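"""AGB regression models and validation metrics.

Four families are supported: SR (simple univariate least squares on the
single best-correlated feature), PLSR (partial least squares), BPNN (a
one-hidden-layer back-propagation network) and RF (random forest).  The
sample table is split 60/20/20 into training, testing and validation by a
seeded random partition with largest-remainder size rounding.

Accuracy is reported as R^2 — the squared Pearson correlation between
predicted and measured AGB — and the RMSE in g/m^2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "FeatureTable",
    "ModelSpec",
    "ValidationReport",
    "FittedModel",
    "split_samples",
    "largest_remainder_sizes",
    "fit_model",
    "evaluate",
    "pearson_r2",
    "rmse",
]

log = logging.getLogger("grassagb")

FAMILIES = ("SR", "PLSR", "BPNN", "RF")


@dataclass
class FeatureTable:
    """Feature matrix X (named columns), target AGB y, sample ids and a
    scale tag ('plot' or 'aggregated-coarse')."""

    X: pd.DataFrame
    y: np.ndarray
    ids: np.ndarray = None
    scale: str = "plot"

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        if len(self.X) != self.y.size:
            raise ValueError("X and y length mismatch")
        if self.X.columns.duplicated().any():
            raise ValueError("feature names must be unique")
        if self.X.isna().any().any() or not np.all(np.isfinite(self.y)):
            raise ValueError("missing values in retained rows")
        if np.any(self.y < 0):
            raise ValueError("AGB must be >= 0")
        if self.ids is None:
            self.ids = np.arange(self.y.size)
        self.ids = np.asarray(self.ids)

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def feature_names(self) -> tuple:
        return tuple(self.X.columns)

    def subset(self, idx) -> "FeatureTable":
        return FeatureTable(self.X.iloc[idx].reset_index(drop=True),
                            self.y[idx], self.ids[idx], self.scale)

    def with_features(self, names) -> "FeatureTable":
        return FeatureTable(self.X[list(names)].copy(), self.y, self.ids, self.scale)


def largest_remainder_sizes(n: int, fractions) -> list:
    """Partition sizes by largest-remainder rounding; ties go to the
    earlier fraction.  Deterministic and covering."""
    exact = [n * f for f in fractions]
    sizes = [int(np.floor(e)) for e in exact]
    rem = n - sum(sizes)
    order = sorted(range(len(fractions)), key=lambda i: (-(exact[i] - sizes[i]), i))
    for i in order[:rem]:
        sizes[i] += 1
    return sizes


def split_samples(table: FeatureTable, fractions=(0.6, 0.2, 0.2), seed: int = 0):
    """Seeded random partition into train/test/validation tables (disjoint,
    covering, reproducible)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if table.n < 5:
        raise ValueError("need at least 5 samples to split")
    sizes = largest_remainder_sizes(table.n, fractions)
    perm = np.random.default_rng(seed).permutation(table.n)
    parts, start = [], 0
    for s in sizes:
        parts.append(table.subset(np.sort(perm[start:start + s])))
        start += s
    return tuple(parts)


@dataclass
class ModelSpec:
    """Regression family, feature set and hyperparameters.

    Defaults (the literature gives none): RF 500 trees / unlimited depth;
    PLSR min(4, n_features - 1) components; BPNN one hidden layer of 16
    units, 2000 epochs, learning rate 0.01."""

    family: str
    features: tuple = ()
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        self.features = tuple(self.features)


@dataclass
class FittedModel:
    spec: ModelSpec
    estimator: object
    feature_names: tuple
    sr_feature: str | None = None
    constant_value: float | None = None

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if self.constant_value is not None:
            return np.full(len(X), self.constant_value)
        if self.spec.family == "SR":
            slope, intercept = self.estimator
            return slope * X[self.sr_feature].to_numpy(dtype=float) + intercept
        return np.asarray(self.estimator.predict(X[list(self.feature_names)]), dtype=float).ravel()


def _best_feature(X: pd.DataFrame, y: np.ndarray) -> str:
    best, best_r = None, -1.0
    for name in X.columns:
        x = X[name].to_numpy(dtype=float)
        if np.std(x) == 0:
            continue
        r = abs(np.corrcoef(x, y)[0, 1])
        if r > best_r:
            best, best_r = name, r
    if best is None:
        raise ValueError("all features are constant")
    return best


def fit_model(spec: ModelSpec, train: FeatureTable) -> FittedModel:
    """Fit one regression family on the training table."""
    if train.n == 0:
        raise ValueError("empty training table")
    names = spec.features or train.feature_names
    X = train.X[list(names)]
    y = train.y
    degenerate = np.std(y) == 0
    if degenerate:
        if spec.family in ("SR", "PLSR"):
            raise ValueError(f"{spec.family}: constant target, fit is degenerate")
        warnings.warn(f"{spec.family}: constant target, returning constant predictor")
        return FittedModel(spec, None, tuple(names), constant_value=float(y[0]))
    hp = spec.hyperparams
    if spec.family == "SR":
        feat = _best_feature(X, y)
        slope, intercept = np.polyfit(X[feat].to_numpy(dtype=float), y, 1)
        return FittedModel(spec, (float(slope), float(intercept)), tuple(names), sr_feature=feat)
    if spec.family == "PLSR":
        n_comp = hp.get("n_components", max(1, min(4, len(names) - 1)))
        est = PLSRegression(n_components=n_comp)
    elif spec.family == "BPNN":
        est = make_pipeline(
            StandardScaler(),
            MLPRegressor(hidden_layer_sizes=(hp.get("hidden", 16),),
                         max_iter=hp.get("epochs", 2000),
                         learning_rate_init=hp.get("learning_rate", 0.01),
                         random_state=spec.seed))
    else:  # RF; mtry = p/3 follows the classic regression-forest convention
        est = RandomForestRegressor(n_estimators=hp.get("n_trees", 500),
                                    max_depth=hp.get("max_depth"),
                                    max_features=hp.get("max_features", 1 / 3),
                                    random_state=spec.seed, n_jobs=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, y)
    return FittedModel(spec, est, tuple(names))


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def pearson_r2(predicted, observed) -> float:
    """Squared Pearson correlation of predictions against measurements;
    NaN (undefined) when either side has zero variance."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    pc, oc = p - p.mean(), o - o.mean()
    denom = np.sqrt((pc ** 2).sum() * (oc ** 2).sum())
    if denom == 0:
        return float("nan")
    return float(((pc * oc).sum() / denom) ** 2)


def rmse(predicted, observed) -> float:
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    return float(np.sqrt(np.mean((p - o) ** 2)))


@dataclass
class ValidationReport:
    n: int
    r2: float
    rmse_g_m2: float
    split: str = ""
    residuals: np.ndarray = None

    def __post_init__(self):
        if self.rmse_g_m2 < 0:
            raise ValueError("RMSE must be >= 0")

    @property
    def r2_defined(self) -> bool:
        return np.isfinite(self.r2)


def evaluate(model: FittedModel, table: FeatureTable, split: str = "") -> ValidationReport:
    """Validate a fitted model: R^2 (squared Pearson) and RMSE (g/m^2)."""
    if table.n == 0:
        raise ValueError("empty evaluation table")
    pred = model.predict(table.X)
    r2 = pearson_r2(pred, table.y)
    if not np.isfinite(r2):
        log.warning("evaluate: R^2 undefined (zero variance); reported as NaN")
    return ValidationReport(table.n, r2, rmse(pred, table.y), split, pred - table.y)
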