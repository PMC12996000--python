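"""Regression models for water-quality retrieval, including the
spectral-space partitioned ensemble (SPE).

Global models (linear regression, random forest, support-vector regression)
fit one relationship to the whole calibration table.  The SPE instead
partitions the predictor (spectral-feature) space into quasi-homogeneous
regions with a shallow regression tree, trains every candidate model inside
each region, keeps the candidate with the lowest cross-validated RMSE, and
routes new spectra to the submodel of their partition.  A global fallback
model serves leaves that cannot support a validated submodel and feature
vectors with missing values.

Evaluation is honest leave-one-out cross-validation: the *entire* procedure
(including the partitioning) is refit on every fold.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from .errors import InsufficientSamplesError, ValidationError
from .matchup import MatchupTable

MODEL_KINDS = ("lr", "rf", "svr")

#: Sentinel leaf id returned by routing when a split feature is nodata.
FALLBACK_LEAF = -1

DEFAULT_RF_PARAMS = {"n_trees": 200, "min_leaf": 3}
DEFAULT_SVR_PARAMS = {"kernel": "rbf", "C": 10.0, "epsilon": 0.1, "standardize": True}
DEFAULT_MAX_DEPTH = 2
DEFAULT_MIN_LEAF_N = 15


@dataclass(frozen=True)
class ModelSpec:
    kind: str
    hyperparameters: tuple = ()  # stored as sorted (key, value) pairs
    seed: int = 0

    def __post_init__(self):
        if self.kind not in MODEL_KINDS:
            raise ValidationError(f"unknown model kind: {self.kind!r}")

    @classmethod
    def make(cls, kind: str, seed: int = 0, **hyper) -> "ModelSpec":
        defaults = {"rf": DEFAULT_RF_PARAMS, "svr": DEFAULT_SVR_PARAMS}.get(kind, {})
        params = {**defaults, **hyper}
        return cls(kind=kind, hyperparameters=tuple(sorted(params.items())), seed=seed)

    @property
    def params(self) -> dict:
        return dict(self.hyperparameters)


def _build_estimator(spec: ModelSpec):
    p = spec.params
    if spec.kind == "lr":
        return LinearRegression()
    if spec.kind == "rf":
        return RandomForestRegressor(
            n_estimators=int(p.get("n_trees", DEFAULT_RF_PARAMS["n_trees"])),
            min_samples_leaf=int(p.get("min_leaf", DEFAULT_RF_PARAMS["min_leaf"])),
            random_state=spec.seed,
        )
    svr = SVR(kernel=p.get("kernel", "rbf"), C=float(p.get("C", 10.0)),
              epsilon=float(p.get("epsilon", 0.1)))
    if p.get("standardize", True):
        return Pipeline([("scale", StandardScaler()), ("svr", svr)])
    return svr


def predict_rows(estimator, X: np.ndarray) -> np.ndarray:
    """Batch-independent prediction: each row's result is bit-identical no
    matter how rows are grouped into batches.

    BLAS matrix products round differently depending on a row's position
    within the batch (vectorized main loop vs remainder), which would break
    the block-size invariance of raster mapping, so linear and SVR
    predictions are evaluated with purely elementwise operations.  Tree
    ensembles traverse per row and are already batch-independent.
    """
    X = np.asarray(X, dtype=np.float64)
    if isinstance(estimator, Pipeline):
        scaler = estimator.named_steps.get("scale")
        inner = estimator.steps[-1][1]
        if scaler is not None:
            X = (X - scaler.mean_) / scaler.scale_
        return predict_rows(inner, X)
    if isinstance(estimator, LinearRegression):
        coef = np.asarray(estimator.coef_, dtype=np.float64).ravel()
        return (X * coef).sum(axis=1) + float(estimator.intercept_)
    if isinstance(estimator, SVR):
        sv = estimator.support_vectors_
        gamma = estimator._gamma
        sq = np.zeros((X.shape[0], sv.shape[0]))
        for f in range(X.shape[1]):
            d = X[:, f, None] - sv[None, :, f]
            sq += d * d
        kernel = np.exp(-gamma * sq)
        dual = np.asarray(estimator.dual_coef_).ravel()
        return (kernel * dual).sum(axis=1) + float(estimator.intercept_[0])
    return estimator.predict(X)


@dataclass
class FittedModel:
    """A fitted global regressor with its spec and feature ordering."""

    spec: ModelSpec
    estimator: object
    feature_names: list[str]
    response_name: str = "response"

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[0] == 0:
            return np.empty(0)
        out = np.full(X.shape[0], np.nan)
        ok = np.all(np.isfinite(X), axis=1)
        if ok.any():
            out[ok] = predict_rows(self.estimator, X[ok])
        return out


def compute_metrics(observed: Sequence[float], predicted: Sequence[float]) -> tuple[float, float, float]:
    """Standard error metrics (R², RMSE, MAE).

    R² = 1 − Σ(o−p)²/Σ(o−ō)²; undefined (NaN) when the observations have
    zero variance.  RMSE and MAE are in response units.
    """
    o = np.asarray(observed, dtype=np.float64)
    p = np.asarray(predicted, dtype=np.float64)
    if o.shape != p.shape or o.ndim != 1:
        raise ValidationError("observed and predicted must be equal-length vectors")
    if o.size < 2:
        raise ValidationError("need at least 2 values")
    if not (np.all(np.isfinite(o)) and np.all(np.isfinite(p))):
        raise ValidationError("metrics require finite inputs")
    sse = float(np.sum((o - p) ** 2))
    sstot = float(np.sum((o - o.mean()) ** 2))
    r2 = 1.0 - sse / sstot if sstot > 0 else float("nan")
    rmse = float(np.sqrt(sse / o.size))
    mae = float(np.mean(np.abs(o - p)))
    return r2, rmse, mae


@dataclass
class ValidationReport:
    r2: float
    rmse: float
    mae: float
    n: int
    per_leaf_n: dict = field(default_factory=dict)
    method: str = "loocv"
    n_fallback_folds: int = 0

    def to_dict(self) -> dict:
        return {
            "r2": self.r2, "rmse": self.rmse, "mae": self.mae, "n": self.n,
            "per_leaf_n": {str(k): v for k, v in self.per_leaf_n.items()},
            "method": self.method, "n_fallback_folds": self.n_fallback_folds,
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        return path


def _table_Xy(table: MatchupTable, feature_names: list[str],
              include_flagged: bool = False) -> tuple[np.ndarray, np.ndarray]:
    return table.to_arrays(feature_names, include_flagged)


def fit_global(spec: ModelSpec, table: MatchupTable,
               feature_names: list[str] | None = None) -> FittedModel:
    """Fit one global regressor on the unflagged matchup rows."""
    feature_names = feature_names or table.feature_names
    X, y = _table_Xy(table, feature_names)
    return fit_global_arrays(spec, X, y, feature_names, table.response_name)


def fit_global_arrays(spec: ModelSpec, X: np.ndarray, y: np.ndarray,
                      feature_names: list[str], response_name: str = "response") -> FittedModel:
    if X.shape[0] < 3:
        raise InsufficientSamplesError(
            f"insufficient samples: {X.shape[0]} usable rows, need >= 3")
    est = _build_estimator(spec)
    est.fit(X, y)
    return FittedModel(spec=spec, estimator=est, feature_names=list(feature_names),
                       response_name=response_name)


def _cv_rmse(spec: ModelSpec, X: np.ndarray, y: np.ndarray,
             selection_cv: str = "loocv", n_folds: int = 5) -> float:
    """Cross-validated RMSE of one candidate on one sample; inf on failure."""
    n = X.shape[0]
    if n < 3:
        return float("inf")
    preds = np.full(n, np.nan)
    if selection_cv == "loocv":
        folds = [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
    elif selection_cv == "kfold":
        kf = KFold(n_splits=min(n_folds, n), shuffle=True, random_state=spec.seed)
        folds = list(kf.split(X))
    else:
        raise ValidationError(f"unknown selection_cv: {selection_cv!r}")
    try:
        for train, test in folds:
            est = _build_estimator(spec)
            est.fit(X[train], y[train])
            preds[test] = est.predict(X[test])
    except Exception:
        return float("inf")
    if not np.all(np.isfinite(preds)):
        return float("inf")
    return float(np.sqrt(np.mean((y - preds) ** 2)))


# --- partition tree ---------------------------------------------------------


@dataclass
class PartitionNode:
    feature_name: str | None  # None for leaves
    split_value: float | None
    left: int | None  # node ids
    right: int | None
    leaf_id: int | None  # set for leaves


@dataclass
class PartitionTree:
    """Axis-aligned binary partition of feature space (go left iff x ≤ split)."""

    nodes: dict[int, PartitionNode]
    root: int
    feature_names: list[str]
    max_depth: int
    min_leaf_n: int

    @property
    def leaf_ids(self) -> list[int]:
        return sorted(n.leaf_id for n in self.nodes.values() if n.leaf_id is not None)

    def route_vector(self, vec: dict[str, float] | np.ndarray) -> int:
        if isinstance(vec, dict):
            vec = np.array([vec[n] for n in self.feature_names], dtype=np.float64)
        node = self.nodes[self.root]
        while node.leaf_id is None:
            x = vec[self.feature_names.index(node.feature_name)]
            if not np.isfinite(x):
                return FALLBACK_LEAF
            node = self.nodes[node.left if x <= node.split_value else node.right]
        return node.leaf_id

    def route_matrix(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        return np.array([self.route_vector(row) for row in X], dtype=int)

    def splits(self) -> list[dict]:
        return [
            {"node": i, "feature": n.feature_name, "split": n.split_value,
             "left": n.left, "right": n.right}
            for i, n in sorted(self.nodes.items()) if n.leaf_id is None
        ]

    @classmethod
    def single_leaf(cls, feature_names: list[str], min_leaf_n: int) -> "PartitionTree":
        return cls(nodes={0: PartitionNode(None, None, None, None, leaf_id=0)},
                   root=0, feature_names=list(feature_names),
                   max_depth=0, min_leaf_n=min_leaf_n)

    @classmethod
    def from_sklearn(cls, tree: DecisionTreeRegressor, feature_names: list[str],
                     max_depth: int, min_leaf_n: int) -> "PartitionTree":
        t = tree.tree_
        nodes: dict[int, PartitionNode] = {}
        for i in range(t.node_count):
            if t.children_left[i] == -1:  # leaf
                nodes[i] = PartitionNode(None, None, None, None, leaf_id=i)
            else:
                nodes[i] = PartitionNode(
                    feature_name=feature_names[t.feature[i]],
                    split_value=float(t.threshold[i]),
                    left=int(t.children_left[i]), right=int(t.children_right[i]),
                    leaf_id=None)
        return cls(nodes=nodes, root=0, feature_names=list(feature_names),
                   max_depth=max_depth, min_leaf_n=min_leaf_n)


@dataclass
class SPEModel:
    """Partition tree + one selected, fitted submodel per leaf + global fallback."""

    tree: PartitionTree
    leaf_models: dict[int, tuple[ModelSpec, object, float]]  # leaf -> (spec, est, score)
    fallback: FittedModel
    feature_names: list[str]  # full predictor set for submodels
    response_name: str = "response"
    warning: str | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        n = X.shape[0]
        if n == 0:
            return np.empty(0)
        part_idx = [self.feature_names.index(f) for f in self.tree.feature_names]
        leaves = self.tree.route_matrix(X[:, part_idx])
        out = np.full(n, np.nan)
        for leaf in np.unique(leaves):
            sel = leaves == leaf
            if leaf == FALLBACK_LEAF or leaf not in self.leaf_models:
                out[sel] = self.fallback.predict(X[sel])
            else:
                _, est, _ = self.leaf_models[leaf]
                rows = X[sel]
                ok = np.all(np.isfinite(rows), axis=1)
                vals = np.full(rows.shape[0], np.nan)
                if ok.any():
                    vals[ok] = predict_rows(est, rows[ok])
                if (~ok).any():
                    vals[~ok] = self.fallback.predict(rows[~ok])
                out[sel] = vals
        return out

    def per_leaf_counts(self, X: np.ndarray) -> dict[int, int]:
        part_idx = [self.feature_names.index(f) for f in self.tree.feature_names]
        leaves = self.tree.route_matrix(np.asarray(X)[:, part_idx])
        return {int(k): int(v) for k, v in zip(*np.unique(leaves, return_counts=True))}

    def manifest(self) -> dict:
        return {
            "kind": "spe",
            "response": self.response_name,
            "feature_names": self.feature_names,
            "partition_features": self.tree.feature_names,
            "max_depth": self.tree.max_depth,
            "min_leaf_n": self.tree.min_leaf_n,
            "splits": self.tree.splits(),
            "leaf_models": {
                str(leaf): {"kind": spec.kind, "seed": spec.seed,
                            "hyperparameters": dict(spec.hyperparameters),
                            "selection_rmse": score}
                for leaf, (spec, _, score) in sorted(self.leaf_models.items())
            },
            "fallback": {"kind": self.fallback.spec.kind,
                         "seed": self.fallback.spec.seed},
        }


def route(spe: SPEModel, feature_vector: dict[str, float] | np.ndarray) -> int:
    """Deterministic descent to a leaf id; FALLBACK_LEAF on nodata splits."""
    if isinstance(feature_vector, dict):
        vec = np.array([feature_vector[f] for f in spe.tree.feature_names])
    else:
        vec = np.asarray(feature_vector, dtype=np.float64)
        if len(vec) == len(spe.feature_names) and spe.feature_names != spe.tree.feature_names:
            idx = [spe.feature_names.index(f) for f in spe.tree.feature_names]
            vec = vec[idx]
    return spe.tree.route_vector(vec)


def predict(spe, rows: np.ndarray) -> np.ndarray:
    """Vectorized prediction preserving input row order (SPE or global model)."""
    return spe.predict(rows)


def _select_leaf_model(X: np.ndarray, y: np.ndarray,
                       candidate_specs: Sequence[ModelSpec],
                       selection_cv: str) -> tuple[ModelSpec, object, float] | None:
    """Score candidates by CV RMSE, refit the winner on all rows.

    Ties break to the earliest candidate in list order (so with LR first, the
    simplest model wins).  Returns None when no candidate can be validated.
    """
    if len(candidate_specs) == 1:
        # nothing to select between; skip the CV and fit directly
        spec, score = candidate_specs[0], float("nan")
    else:
        scores = [_cv_rmse(s, X, y, selection_cv) for s in candidate_specs]
        best = int(np.argmin(scores))  # argmin takes first on ties
        if not np.isfinite(scores[best]):
            return None
        spec, score = candidate_specs[best], scores[best]
    est = _build_estimator(spec)
    try:
        est.fit(X, y)
    except Exception:
        return None
    return spec, est, float(score)


def fit_spe(table: MatchupTable, candidate_specs: Sequence[ModelSpec],
            partition_features: list[str] | None = None,
            max_depth: int = DEFAULT_MAX_DEPTH,
            min_leaf_n: int = DEFAULT_MIN_LEAF_N,
            selection_cv: str = "loocv", seed: int = 0) -> SPEModel:
    """Fit the spectral-space partitioned ensemble.

    1. A variance-reducing regression tree on ``partition_features`` (default:
       all features) vs the response defines the partition, grown to
       ``max_depth`` with at least ``min_leaf_n`` rows per leaf.
    2. Within each leaf every candidate spec is scored by ``selection_cv``
       RMSE; the lowest-RMSE candidate is refit on all leaf rows and stored.
    3. A global fallback (the best candidate by whole-table CV) covers leaves
       that fail and vectors with missing split features.

    ``max_depth`` 0 degenerates to the best global candidate.
    """
    if min_leaf_n < 5:
        raise ValidationError("min_leaf_n must be >= 5")
    if not candidate_specs:
        raise ValidationError("need at least one candidate spec")
    feature_names = list(table.feature_names)
    partition_features = list(partition_features or feature_names)
    unknown = set(partition_features) - set(feature_names)
    if unknown:
        raise ValidationError(f"partition features not in table: {sorted(unknown)}")

    X, y = table.to_arrays(feature_names)
    n = X.shape[0]
    if n < 2 * min_leaf_n:
        raise InsufficientSamplesError(
            f"insufficient samples: {n} usable rows, need >= {2 * min_leaf_n}")

    # global fallback = best candidate by whole-table CV
    if len(candidate_specs) == 1:
        fb_scores, fb_idx = [float("nan")], 0
    else:
        fb_scores = [_cv_rmse(s, X, y, selection_cv) for s in candidate_specs]
        fb_idx = int(np.argmin(fb_scores))
    fallback = fit_global_arrays(candidate_specs[fb_idx], X, y, feature_names,
                                 table.response_name)

    warning = None
    if max_depth <= 0:
        tree = PartitionTree.single_leaf(partition_features, min_leaf_n)
        leaf_models = {0: (fallback.spec, fallback.estimator,
                           float(fb_scores[fb_idx]))}
        return SPEModel(tree=tree, leaf_models=leaf_models, fallback=fallback,
                        feature_names=feature_names,
                        response_name=table.response_name)

    part_idx = [feature_names.index(f) for f in partition_features]
    sk_tree = DecisionTreeRegressor(max_depth=max_depth,
                                    min_samples_leaf=min_leaf_n,
                                    random_state=seed)
    sk_tree.fit(X[:, part_idx], y)
    tree = PartitionTree.from_sklearn(sk_tree, partition_features, max_depth, min_leaf_n)

    leaf_assign = tree.route_matrix(X[:, part_idx])
    leaf_models: dict[int, tuple[ModelSpec, object, float]] = {}
    n_failed = 0
    for leaf in tree.leaf_ids:
        rows = leaf_assign == leaf
        selected = _select_leaf_model(X[rows], y[rows], candidate_specs, selection_cv)
        if selected is None:
            n_failed += 1
            continue  # leaf served by fallback
        leaf_models[leaf] = selected
    if not leaf_models:
        warning = "all leaves degenerate; SPE reduces to the global model"
        tree = PartitionTree.single_leaf(partition_features, min_leaf_n)
        leaf_models = {0: (fallback.spec, fallback.estimator, float(fb_scores[fb_idx]))}
    return SPEModel(tree=tree, leaf_models=leaf_models, fallback=fallback,
                    feature_names=feature_names, response_name=table.response_name,
                    warning=warning)


def loocv(fit_procedure: Callable[[MatchupTable], object],
          table: MatchupTable) -> ValidationReport:
    """Honest leave-one-out cross-validation of a whole fitting procedure.

    Every fold refits the entire procedure — including, for the SPE, the
    partition itself — on all rows but one, then predicts the held-out row.
    A fold whose fit fails contributes a global linear-fallback prediction
    and is counted in ``n_fallback_folds``.
    """
    rows = table.usable_rows()
    n = len(rows)
    if n < 3:
        raise InsufficientSamplesError(f"insufficient samples for LOOCV: {n}")
    names = table.feature_names
    y = np.array([r.station.response_value for r in rows])
    X = np.array([[r.predictors[f] for f in names] for r in rows])
    preds = np.full(n, np.nan)
    n_fallback = 0
    for i in range(n):
        sub = MatchupTable(rows=rows[:i] + rows[i + 1:], feature_names=names,
                           response_name=table.response_name)
        try:
            model = fit_procedure(sub)
            preds[i] = model.predict(X[i][None, :])[0]
        except Exception:
            model = None
        if model is None or not np.isfinite(preds[i]):
            # fold failed to fit: fall back to a plain least-squares line on
            # the fold's training rows (flagged in the report)
            n_fallback += 1
            Xs, ys = sub.to_arrays(names)
            emergency = LinearRegression().fit(Xs, ys)
            preds[i] = emergency.predict(X[i][None, :])[0]
    r2, rmse, mae = compute_metrics(y, preds)
    per_leaf: dict = {}
    final = fit_procedure(table)
    if isinstance(final, SPEModel):
        per_leaf = final.per_leaf_counts(X)
    return ValidationReport(r2=r2, rmse=rmse, mae=mae, n=n, per_leaf_n=per_leaf,
                            method="loocv", n_fallback_folds=n_fallback)


# --- persistence ------------------------------------------------------------


def save_model(model: FittedModel | SPEModel, path: str | Path) -> Path:
    """Persist a fitted model: pickled submodels + a JSON manifest sidecar."""
    path = Path(path)
    if isinstance(model, SPEModel):
        manifest = model.manifest()
    else:
        manifest = {"kind": model.spec.kind, "seed": model.spec.seed,
                    "hyperparameters": dict(model.spec.hyperparameters),
                    "feature_names": model.feature_names,
                    "response": model.response_name}
    with open(path, "wb") as fh:
        pickle.dump({"manifest": manifest, "model": model}, fh)
    path.with_suffix(path.suffix + ".manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n")
    return path


def load_model(path: str | Path):
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    return payload["model"]
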