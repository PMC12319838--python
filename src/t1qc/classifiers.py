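"""Random-undersampling boosting (RUSBoost) and baseline classifiers.

The QC problem is heavily imbalanced: reject scans are typically 5-10% of a
curated cohort. RUSBoost addresses this by rebalancing every boosting cycle:
all minority-class rows are kept and the majority class is subsampled down to
the minority count (by default with probability proportional to the current
boosting weights) before fitting a depth-limited decision tree. Weighted
error is evaluated on the FULL training set, the cycle weight is
``alpha_t = learning_rate * 1/2 * ln((1 - eps_t) / eps_t)`` and the usual
multiplicative AdaBoost weight update follows. The ensemble score is
``sum_t alpha_t * h_t(x)`` with ``h_t in {-1, +1}`` (+1 = reject); a score of
exactly 0 ties toward reject, since the framework is tuned to minimise
poor-quality scans slipping through.

SVM and random-forest baselines wrap scikit-learn estimators behind the same
predict interface. Weak learners are serialised to JSON as explicit node
arrays, so a reloaded model reproduces scores bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .core_io import ACCEPT, REJECT, LabelSet

MODEL_SCHEMA_VERSION = 1

#: default hyperparameter grids
RUS_GRID = {"max_splits": (10, 50), "n_cycles": (10, 50, 100), "learning_rate": (0.01, 0.1)}
SVM_GRID = {"box_constraint": (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0), "kernel": ("linear", "rbf")}
RF_GRID = {"max_splits": (10, 50), "n_cycles": (10, 50, 100)}


@dataclass(frozen=True)
class RUSHyper:
    max_splits: int = 50
    n_cycles: int = 100
    learning_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.max_splits < 1 or self.n_cycles < 1:
            raise ValueError("max_splits and n_cycles must be positive")
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must lie in (0, 1]")


@dataclass(frozen=True)
class SVMHyper:
    box_constraint: float = 1.0
    kernel: str = "rbf"

    def __post_init__(self) -> None:
        if self.box_constraint <= 0:
            raise ValueError("box_constraint must be positive")
        if self.kernel not in ("linear", "rbf"):
            raise ValueError("kernel must be 'linear' or 'rbf'")


@dataclass(frozen=True)
class RFHyper:
    max_splits: int = 50
    n_cycles: int = 100

    def __post_init__(self) -> None:
        if self.max_splits < 1 or self.n_cycles < 1:
            raise ValueError("max_splits and n_cycles must be positive")


# ---------------------------------------------------------------------------
# helpers


def _as_signed(y) -> np.ndarray:
    """Labels -> {-1 accept, +1 reject}."""
    if isinstance(y, LabelSet):
        y = y.labels
    arr = np.asarray(y)
    if arr.dtype.kind in "USO":
        bad = set(np.unique(arr)) - {ACCEPT, REJECT}
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}")
        return np.where(arr == REJECT, 1, -1)
    return np.where(arr.astype(int) > 0, 1, -1)


def _signed_to_labels(signed: np.ndarray, index) -> LabelSet:
    values = np.where(signed > 0, REJECT, ACCEPT)
    return LabelSet(pd.Series(values, index=index), provenance="predicted")


def _as_matrix(X, feature_names: list[str] | None):
    """Extract (array, index, names); realign DataFrame columns by name."""
    if isinstance(X, pd.DataFrame):
        if feature_names is not None:
            missing = [f for f in feature_names if f not in X.columns]
            if missing:
                raise KeyError(f"feature(s) missing from input: {missing[:5]}")
            X = X[feature_names]
        return X.to_numpy(dtype=float), X.index, list(X.columns)
    arr = np.asarray(X, dtype=float)
    if feature_names is not None and arr.ndim == 2 and arr.shape[1] != len(feature_names):
        raise ValueError(
            f"expected {len(feature_names)} features, got {arr.shape[1]}"
        )
    return arr, pd.RangeIndex(len(arr)), feature_names


# ---------------------------------------------------------------------------
# frozen decision tree (serialisable weak learner)


@dataclass
class FrozenTree:
    """Decision tree as plain node arrays (feature < 0 marks a leaf)."""

    children_left: list[int]
    children_right: list[int]
    feature: list[int]
    threshold: list[float]
    leaf_sign: list[int]

    @classmethod
    def from_sklearn(cls, tree: DecisionTreeClassifier) -> "FrozenTree":
        t = tree.tree_
        # per-leaf vote: majority class, mapped to -1 accept / +1 reject
        classes = np.asarray(tree.classes_)
        sign_of_class = np.where(classes > 0, 1, -1)
        leaf_sign = sign_of_class[t.value[:, 0, :].argmax(axis=1)]
        return cls(
            children_left=t.children_left.tolist(),
            children_right=t.children_right.tolist(),
            feature=t.feature.tolist(),
            threshold=t.threshold.tolist(),
            leaf_sign=[int(s) for s in leaf_sign],
        )

    def predict_sign(self, X: np.ndarray) -> np.ndarray:
        left = np.asarray(self.children_left)
        right = np.asarray(self.children_right)
        feat = np.asarray(self.feature)
        thr = np.asarray(self.threshold)
        sign = np.asarray(self.leaf_sign)
        pos = np.zeros(len(X), dtype=np.int64)
        while True:
            f = feat[pos]
            active = f >= 0
            if not active.any():
                break
            rows = np.flatnonzero(active)
            go_left = X[rows, f[rows]] <= thr[pos[rows]]
            pos[rows] = np.where(go_left, left[pos[rows]], right[pos[rows]])
        return sign[pos]

    def to_dict(self) -> dict:
        return {
            "children_left": self.children_left,
            "children_right": self.children_right,
            "feature": self.feature,
            "threshold": self.threshold,
            "leaf_sign": self.leaf_sign,
        }


# ---------------------------------------------------------------------------
# RUSBoost


def undersample_majority(y, weights, seed) -> np.ndarray:
    """Indices of a class-balanced subset: all minority + weight-proportional
    sample of the majority (without replacement) down to the minority count.

    Already-balanced input is returned unchanged. Deterministic given seed.
    """
    signed = _as_signed(y)
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(signed):
        raise ValueError("weights and labels are not aligned")
    n_rej = int((signed > 0).sum())
    n_acc = len(signed) - n_rej
    if n_rej == 0 or n_acc == 0:
        raise ValueError("both classes must be present to undersample")
    if n_rej == n_acc:
        return np.arange(len(signed))
    minority_sign = 1 if n_rej < n_acc else -1
    min_idx = np.flatnonzero(signed == minority_sign)
    maj_idx = np.flatnonzero(signed != minority_sign)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = weights[maj_idx]
    if w.sum() <= 0:
        raise ValueError("majority-class weights sum to zero")
    chosen = rng.choice(maj_idx, size=len(min_idx), replace=False, p=w / w.sum())
    return np.sort(np.concatenate([min_idx, chosen]))


@dataclass
class RUSBoostModel:
    """Boosted ensemble of depth-limited trees with per-cycle weights."""

    weak_learners: list[FrozenTree]
    alphas: list[float]
    learning_rate: float
    feature_names: list[str] | None
    seed: int
    hyper: RUSHyper
    classes: tuple[str, str] = (ACCEPT, REJECT)

    def __post_init__(self) -> None:
        if len(self.weak_learners) != len(self.alphas):
            raise ValueError("one alpha per weak learner required")

    @property
    def n_cycles_kept(self) -> int:
        return len(self.weak_learners)

    def decision_scores(self, X) -> pd.Series:
        arr, index, _ = _as_matrix(X, self.feature_names)
        scores = np.zeros(len(arr))
        for alpha, tree in zip(self.alphas, self.weak_learners):
            scores += alpha * tree.predict_sign(arr)
        return pd.Series(scores, index=index, name="score")

    def predict(self, X) -> tuple[pd.Series, LabelSet]:
        """Ensemble scores and labels; score >= 0 -> reject (tie to reject)."""
        scores = self.decision_scores(X)
        signed = np.where(scores.to_numpy() >= 0, 1, -1)
        return scores, _signed_to_labels(signed, scores.index)

    # -- persistence ----------------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            "schema_version": MODEL_SCHEMA_VERSION,
            "model": "rusboost",
            "learning_rate": self.learning_rate,
            "seed": self.seed,
            "hyper": {
                "max_splits": self.hyper.max_splits,
                "n_cycles": self.hyper.n_cycles,
                "learning_rate": self.hyper.learning_rate,
            },
            "classes": list(self.classes),
            "feature_names": self.feature_names,
            "alphas": self.alphas,
            "weak_learners": [t.to_dict() for t in self.weak_learners],
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source) -> "RUSBoostModel":
        is_path = isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        )
        if is_path:
            payload = json.loads(Path(source).read_text(encoding="utf-8"))
        else:
            payload = json.loads(source)
        if payload.get("model") != "rusboost":
            raise ValueError("not a serialised RUSBoost model")
        return cls(
            weak_learners=[FrozenTree(**t) for t in payload["weak_learners"]],
            alphas=[float(a) for a in payload["alphas"]],
            learning_rate=float(payload["learning_rate"]),
            feature_names=payload["feature_names"],
            seed=int(payload["seed"]),
            hyper=RUSHyper(**payload["hyper"]),
            classes=tuple(payload["classes"]),
        )


def train_rusboost(
    X,
    y,
    hyper: RUSHyper = RUSHyper(),
    seed: int = 0,
    sample_mode: str = "weighted",
    max_retries: int = 10,
) -> RUSBoostModel:
    """Train a RUSBoost ensemble.

    Each cycle draws a balanced undersample from the current boosting weights
    (``sample_mode='uniform'`` ignores the weights when subsampling), fits a
    tree with at most ``hyper.max_splits`` internal splits, and keeps the
    cycle only if its weighted error on the full training set is below 0.5
    (otherwise it is discarded and resampled, up to ``max_retries`` times; if
    retries are exhausted boosting stops early). A zero-error cycle has its
    error floored at 1/(2n) to cap alpha.
    """
    if sample_mode not in ("weighted", "uniform"):
        raise ValueError("sample_mode must be 'weighted' or 'uniform'")
    arr, _, names = _as_matrix(X, None)
    if not np.isfinite(arr).all():
        raise ValueError("feature matrix must be finite")
    signed = _as_signed(y)
    if len(signed) != len(arr):
        raise ValueError("X and y are not aligned")
    if len(np.unique(signed)) < 2:
        raise ValueError("both classes must be present")

    n = len(arr)
    rng = np.random.default_rng(seed)
    weights = np.full(n, 1.0 / n)
    trees: list[FrozenTree] = []
    alphas: list[float] = []

    for _ in range(hyper.n_cycles):
        kept = False
        for _retry in range(max_retries):
            sample_w = weights if sample_mode == "weighted" else np.full(n, 1.0 / n)
            idx = undersample_majority(signed, sample_w, rng)
            learner = DecisionTreeClassifier(
                max_leaf_nodes=hyper.max_splits + 1,
                random_state=int(rng.integers(2**31)),
            )
            learner.fit(arr[idx], signed[idx], sample_weight=weights[idx])
            tree = FrozenTree.from_sklearn(learner)
            h = tree.predict_sign(arr)
            eps = float(weights[h != signed].sum())
            if eps < 0.5:
                kept = True
                break
        if not kept:
            break
        eps = max(eps, 1.0 / (2 * n))  # cap alpha when the cycle is perfect
        alpha = hyper.learning_rate * 0.5 * np.log((1.0 - eps) / eps)
        trees.append(tree)
        alphas.append(float(alpha))
        weights = weights * np.exp(-alpha * signed * h)
        weights /= weights.sum()

    if not trees:
        raise RuntimeError("all boosting cycles were discarded (weighted error >= 0.5)")
    return RUSBoostModel(
        weak_learners=trees,
        alphas=alphas,
        learning_rate=hyper.learning_rate,
        feature_names=names,
        seed=seed,
        hyper=hyper,
    )


# ---------------------------------------------------------------------------
# baselines


@dataclass
class BaselineModel:
    """scikit-learn SVM or random-forest behind the common predict interface."""

    kind: str
    estimator: object
    feature_names: list[str] | None
    hyper: object
    seed: int

    def decision_scores(self, X) -> pd.Series:
        arr, index, _ = _as_matrix(X, self.feature_names)
        if len(arr) == 0:
            return pd.Series(np.empty(0), index=index, name="score")
        if self.kind == "svm":
            raw = self.estimator.decision_function(arr)
            # orient so positive = reject
            if self.estimator.classes_[1] != 1:
                raw = -raw
            return pd.Series(raw, index=index, name="score")
        proba = self.estimator.predict_proba(arr)
        rej_col = int(np.flatnonzero(self.estimator.classes_ == 1)[0])
        return pd.Series(proba[:, rej_col] - 0.5, index=index, name="score")

    def predict(self, X) -> tuple[pd.Series, LabelSet]:
        scores = self.decision_scores(X)
        signed = np.where(scores.to_numpy() >= 0, 1, -1)
        return scores, _signed_to_labels(signed, scores.index)


def train_baseline(X, y, kind: str, hyper=None, seed: int = 0) -> BaselineModel:
    """Train an SVM ('svm') or bagged-tree random forest ('rf') baseline.

    The RF honours the same split cap as RUSBoost (``max_splits`` internal
    splits per tree, ``n_cycles`` trees). SVM inputs are assumed standardised
    upstream (the pipeline z-scores features before training).
    """
    arr, _, names = _as_matrix(X, None)
    signed = _as_signed(y)
    if len(np.unique(signed)) < 2:
        raise ValueError("both classes must be present")
    if kind == "svm":
        hyper = hyper or SVMHyper()
        est = SVC(C=hyper.box_constraint, kernel=hyper.kernel, random_state=seed)
    elif kind == "rf":
        hyper = hyper or RFHyper()
        est = RandomForestClassifier(
            n_estimators=hyper.n_cycles,
            max_leaf_nodes=hyper.max_splits + 1,
            random_state=seed,
            n_jobs=1,
        )
    else:
        raise ValueError(f"unknown baseline kind {kind!r}; expected 'svm' or 'rf'")
    est.fit(arr, signed)
    return BaselineModel(kind=kind, estimator=est, feature_names=names, hyper=hyper, seed=seed)


def predict(model, X) -> tuple[pd.Series, LabelSet]:
    """Scores and accept/reject labels from any trained model.

    Deterministic; DataFrame inputs are realigned to the model's feature
    names, so permuting columns does not change predictions. Empty input
    yields empty outputs.
    """
    if isinstance(X, pd.DataFrame) and len(X) == 0:
        empty = pd.Series(np.empty(0), index=X.index, name="score")
        return empty, _signed_to_labels(np.empty(0, dtype=int), X.index)
    return model.predict(X)


def grid_combinations(kind: str, grid: dict | None = None):
    """Enumerate hyperparameter objects for a classifier kind's grid."""
    if kind == "rus":
        grid = grid or RUS_GRID
        return [
            RUSHyper(ms, nc, lr)
            for ms in grid["max_splits"]
            for nc in grid["n_cycles"]
            for lr in grid["learning_rate"]
        ]
    if kind == "rf":
        grid = grid or RF_GRID
        return [RFHyper(ms, nc) for ms in grid["max_splits"] for nc in grid["n_cycles"]]
    if kind == "svm":
        grid = grid or SVM_GRID
        return [SVMHyper(c, k) for c in grid["box_constraint"] for k in grid["kernel"]]
    raise ValueError(f"unknown classifier kind {kind!r}")


def smaller_model_key(kind: str, hyper):
    """Sort key implementing the 'prefer smaller models' tie-break."""
    if kind == "rus":
        return (hyper.n_cycles, hyper.max_splits, hyper.learning_rate)
    if kind == "rf":
        return (hyper.n_cycles, hyper.max_splits)
    if kind == "svm":
        return (hyper.kernel != "linear", hyper.box_constraint)
    raise ValueError(f"unknown classifier kind {kind!r}")


def train_classifier(X, y, kind: str, hyper, seed: int = 0):
    """Uniform training entry point for 'rus', 'svm', and 'rf'."""
    if kind == "rus":
        return train_rusboost(X, y, hyper or RUSHyper(), seed=seed)
    return train_baseline(X, y, kind, hyper, seed=seed)
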