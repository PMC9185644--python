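"""Feature selection, grid-searched training and persistence of side models.

Each side (left/right) gets one 3-class classifier chosen by exhaustive
grid search over three algorithm families -- SVM, k-nearest neighbours
and random forest -- with seeded stratified 10-fold cross-validation.
Univariate ANOVA-F feature selection caps the input at Nfmax = 30
features and, by default, is fitted inside every training fold so the
reported CV accuracy carries no selection leakage (``select_in_fold``
reproduces the optimistic whole-set variant).

Because consecutive windows overlap, windows from one trial are highly
correlated; the default CV protocol keeps each trial's windows in a
single fold (``group_by_trial``).  The pooled (window-level stratified)
score is also computed for the selected model, since pooled CV is what
sliding-window studies usually report.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import f_classif
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .windowing import LabeledDataset, WindowParams

__all__ = [
    "GRID",
    "TrainingConfig",
    "SideModel",
    "select_features",
    "grid_search",
    "train_side",
    "sweep_window_params",
    "save_model",
    "load_model",
]

#: Hyperparameter grids, one dict of lists per algorithm family.
GRID: dict[str, dict[str, list]] = {
    "svm": {
        "kernel": ["linear", "rbf"],
        "C": [0.1, 0.3, 0.6, 1.0, 3, 6, 10],
    },
    "knn": {
        "n_neighbors": [3, 5, 10, 15, 20, 40],
        "weights": ["uniform", "distance"],
        "algorithm": ["auto", "ball_tree", "kd_tree", "brute"],
    },
    "random_forest": {
        "n_estimators": [50, 100, 200],
        "criterion": ["gini", "entropy"],
        "max_depth": [5, 8, 11, 14],
        "max_features": ["auto", "sqrt", "log2"],
    },
}

ALGORITHMS = tuple(GRID)


@dataclass(frozen=True)
class TrainingConfig:
    n_folds: int = 10
    nf_max: int = 30
    seed: int = 0
    select_in_fold: bool = True
    group_by_trial: bool = True
    window_sweep_w: tuple[int, ...] = (10, 20, 30)
    window_sweep_s: tuple[int, ...] = (3, 5)

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.nf_max < 1:
            raise ValueError("nf_max must be >= 1")


def select_features(X: pd.DataFrame, y: np.ndarray, k: int) -> list[str]:
    """Top-k feature names by univariate ANOVA F-score across classes.

    Deterministic: ties (and duplicate columns) break by column name.
    Constant columns score 0.
    """
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds the {X.shape[1]} available features")
    with np.errstate(divide="ignore", invalid="ignore"):
        F, _ = f_classif(X.to_numpy(), y)
    F = np.nan_to_num(F, nan=0.0, posinf=np.finfo(float).max)
    ranked = sorted(zip(-F, X.columns), key=lambda t: (t[0], t[1]))
    return [name for _, name in ranked[:k]]


class TopKAnovaSelector(BaseEstimator, TransformerMixin):
    """sklearn transformer wrapping :func:`select_features` (fold-safe)."""

    def __init__(self, k: int = 30):
        self.k = k

    def fit(self, X: pd.DataFrame, y=None):
        self.selected_ = select_features(X, np.asarray(y), min(self.k, X.shape[1]))
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        return X[self.selected_].to_numpy()


class NamedColumnSelector(BaseEstimator, TransformerMixin):
    """Select a frozen list of feature columns (pre-fitted selection)."""

    def __init__(self, columns: list[str]):
        self.columns = columns

    def fit(self, X, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        return X[self.columns].to_numpy()


def _estimator(algo: str, params: dict, seed: int) -> BaseEstimator:
    params = dict(params)
    if algo == "svm":
        return SVC(random_state=seed, **params)
    if algo == "knn":
        return KNeighborsClassifier(**params)
    if algo == "random_forest":
        # "auto" is the historical alias for sqrt
        if params.get("max_features") == "auto":
            params["max_features"] = "sqrt"
        return RandomForestClassifier(random_state=seed, **params)
    raise ValueError(f"unknown algorithm {algo!r}; expected one of {ALGORITHMS}")


def _pipeline(algo: str, params: dict, cfg: TrainingConfig, selector) -> Pipeline:
    steps = [("select", selector)]
    if algo in ("svm", "knn"):
        # distance-based models need commensurate feature scales
        steps.append(("scale", StandardScaler()))
    steps.append(("clf", _estimator(algo, params, cfg.seed)))
    return Pipeline(steps)


def _cv_splits(y, groups, cfg: TrainingConfig):
    if cfg.group_by_trial and groups is not None and len(np.unique(groups)) >= cfg.n_folds:
        cv = StratifiedGroupKFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
        return list(cv.split(np.zeros(len(y)), y, groups))
    cv = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
    return list(cv.split(np.zeros(len(y)), y))


def _pooled_splits(y, cfg: TrainingConfig):
    cv = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
    return list(cv.split(np.zeros(len(y)), y))


def cross_val_accuracy(
    pipe: Pipeline, X: pd.DataFrame, y: np.ndarray, splits
) -> tuple[float, np.ndarray]:
    """Mean accuracy and per-fold scores over precomputed splits."""
    scores = []
    for tr, te in splits:
        model = clone(pipe)
        model.fit(X.iloc[tr], y[tr])
        scores.append(float(np.mean(model.predict(X.iloc[te]) == y[te])))
    scores = np.asarray(scores)
    return float(scores.mean()), scores


def _grid_points(algo: str) -> list[dict]:
    grid = GRID[algo]
    keys = sorted(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def grid_search(
    X: pd.DataFrame,
    y: np.ndarray,
    algo: str,
    cfg: TrainingConfig,
    groups: np.ndarray | None = None,
) -> tuple[dict, float]:
    """Exhaustive search of one algorithm's grid; returns (params, cv accuracy).

    All grid points share one set of seeded CV folds, so the winner is
    invariant to enumeration order; exact score ties break on the
    canonical (sorted-JSON) parameter string.
    """
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < cfg.n_folds:
        raise ValueError(
            f"class {classes[counts.argmin()]!r} has {counts.min()} samples, "
            f"fewer than n_folds={cfg.n_folds}"
        )
    splits = _cv_splits(y, groups, cfg)
    if cfg.select_in_fold:
        selector = TopKAnovaSelector(k=cfg.nf_max)
    else:
        selector = NamedColumnSelector(select_features(X, y, min(cfg.nf_max, X.shape[1])))
    best: tuple[float, str, dict] | None = None
    for params in _grid_points(algo):
        acc, _ = cross_val_accuracy(_pipeline(algo, params, cfg, selector), X, y, splits)
        key = json.dumps(params, sort_keys=True, default=str)
        if best is None or (-acc, key) < (best[0], best[1]):
            best = (-acc, key, params)
    assert best is not None
    return best[2], -best[0]


@dataclass
class SideModel:
    """A trained per-side 3-class classifier plus its provenance."""

    side: str
    mode: str
    algorithm: str
    params: dict
    selected_features: list[str]
    cv_accuracy: float
    cv_accuracy_pooled: float
    window_params: WindowParams
    seed: int
    pipeline: Pipeline = field(repr=False)
    feature_names: list[str] = field(default_factory=list, repr=False)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.pipeline.predict(X)


def train_side(
    dataset: LabeledDataset,
    cfg: TrainingConfig,
    algos: tuple[str, ...] = ALGORITHMS,
) -> SideModel:
    """Grid-search the requested algorithms and refit the winner on all data."""
    results = {}
    for algo in algos:
        params, acc = grid_search(dataset.X, dataset.y, algo, cfg, groups=dataset.groups)
        results[algo] = (params, acc)
    best_algo = min(results, key=lambda a: (-results[a][1], a))
    params, acc = results[best_algo]

    selected = select_features(dataset.X, dataset.y, min(cfg.nf_max, dataset.X.shape[1]))
    final = _pipeline(best_algo, params, cfg, NamedColumnSelector(selected))
    final.fit(dataset.X, dataset.y)

    pooled_pipe = _pipeline(
        best_algo,
        params,
        cfg,
        TopKAnovaSelector(k=cfg.nf_max)
        if cfg.select_in_fold
        else NamedColumnSelector(selected),
    )
    pooled_acc, _ = cross_val_accuracy(
        pooled_pipe, dataset.X, dataset.y, _pooled_splits(dataset.y, cfg)
    )

    return SideModel(
        side=dataset.side,
        mode=dataset.mode,
        algorithm=best_algo,
        params=params,
        selected_features=selected,
        cv_accuracy=acc,
        cv_accuracy_pooled=pooled_acc,
        window_params=dataset.params,
        seed=cfg.seed,
        pipeline=final,
        feature_names=list(dataset.X.columns),
    )


def sweep_window_params(
    trials,
    side: str,
    mode: str,
    cfg: TrainingConfig,
    algos: tuple[str, ...] = ALGORITHMS,
) -> pd.DataFrame:
    """CV accuracy for every (algorithm, w, s) combination.

    Returns a tidy frame with columns algo/w/s/cv_accuracy -- the window
    parameter sweep used to pick (w, s) for the deployed models.
    """
    from .windowing import build_dataset

    rows = []
    for w in cfg.window_sweep_w:
        for s in cfg.window_sweep_s:
            ds = build_dataset(trials, side, mode, WindowParams(w, s), seed=cfg.seed)
            for algo in algos:
                params, acc = grid_search(ds.X, ds.y, algo, cfg, groups=ds.groups)
                rows.append(
                    {"algo": algo, "w": w, "s": s, "cv_accuracy": acc,
                     "best_params": json.dumps(params, sort_keys=True, default=str)}
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# persistence

SCHEMA_VERSION = 1


def _model_hash(meta: dict) -> str:
    blob = json.dumps(meta, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def save_model(model: SideModel, path: str | Path) -> Path:
    path = Path(path)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "side": model.side,
        "mode": model.mode,
        "algorithm": model.algorithm,
        "params": model.params,
        "selected_features": model.selected_features,
        "cv_accuracy": model.cv_accuracy,
        "cv_accuracy_pooled": model.cv_accuracy_pooled,
        "window_params": {"w": model.window_params.w, "s": model.window_params.s},
        "seed": model.seed,
        "feature_names": model.feature_names,
    }
    joblib.dump({"meta": meta, "hash": _model_hash(meta), "pipeline": model.pipeline}, path)
    return path


def load_model(path: str | Path) -> SideModel:
    payload = joblib.load(path)
    meta = payload["meta"]
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema version {meta.get('schema_version')}")
    if _model_hash(meta) != payload["hash"]:
        raise ValueError("model metadata hash mismatch; file corrupted or tampered")
    return SideModel(
        side=meta["side"],
        mode=meta["mode"],
        algorithm=meta["algorithm"],
        params=meta["params"],
        selected_features=meta["selected_features"],
        cv_accuracy=meta["cv_accuracy"],
        cv_accuracy_pooled=meta["cv_accuracy_pooled"],
        window_params=WindowParams(**meta["window_params"]),
        seed=meta["seed"],
        pipeline=payload["pipeline"],
        feature_names=meta["feature_names"],
    )
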