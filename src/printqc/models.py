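"""Seven classical learners with hyperparameter grid search.

Techniques: logistic regression (LR), decision tree (DT), random forest
(RF), gradient boosting (GB), multi-layer perceptron (MLP), RBF support
vector machine (SVM) and k-nearest neighbors (kNN), all via scikit-learn.

Tuning is an exhaustive loop over the declared grid in declared order with
stratified cross-validated accuracy; ties go to the first candidate. A
cooperative resource budget lets a fit report "exceeded limits" instead of
crashing — large feature spaces genuinely push some learners (notably LR)
past practical limits, and that outcome must be representable in reports.

Class convention: labels are the strings 'bad' and 'good'; the positive
class is 'good' and probability columns are ordered (bad, good). Predicted
label is the argmax probability with ties resolved to 'bad' — the
conservative choice for quality control.
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from printqc.preprocess import FeatureMatrix

TECHNIQUES = ("LR", "DT", "RF", "GB", "MLP", "SVM", "kNN")
CLASS_ORDER = ("bad", "good")

#: default hyperparameter grids (insertion order is the tie-break order)
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "DT": {"max_depth": [3, 5, 10, None], "min_samples_leaf": [1, 5]},
    "RF": {"n_estimators": [5, 10, 50, 100], "max_depth": [3, 5, 10, None]},
    "GB": {"n_estimators": [50, 100], "learning_rate": [0.1, 0.3], "max_depth": [2, 3]},
    "MLP": {"hidden_layer_sizes": [(64,), (256,)]},
    "SVM": {"C": [0.1, 1, 10], "gamma": ["scale", 1e-4]},
    "kNN": {"n_neighbors": [1, 3, 5, 11]},
    "LR": {"C": [0.01, 0.1, 1]},
}


@dataclass(frozen=True)
class ModelSpec:
    """One technique plus its tuning protocol."""

    technique: str
    grid: dict[str, list] | None = None  # None => DEFAULT_GRIDS when tuned
    cv_folds: int = 5
    scoring: str = "accuracy"
    seed: int = 0
    tuned: bool = True
    fixed_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.technique not in TECHNIQUES:
            raise ValueError(f"unknown technique {self.technique!r}; expected {TECHNIQUES}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.scoring != "accuracy":
            raise ValueError("only accuracy scoring is supported")
        if self.tuned and self.grid is not None and not self.grid:
            raise ValueError("grid must be non-empty when tuned")

    def resolved_grid(self) -> dict[str, list]:
        return self.grid if self.grid is not None else DEFAULT_GRIDS[self.technique]


@dataclass(frozen=True)
class TrainBudget:
    """Cooperative per-fit resource cap, checked between grid candidates."""

    wall_time_s: float | None = None
    max_features: int | None = None


@dataclass
class ExceededLimits:
    """Structured record of a fit aborted by its resource budget."""

    spec: ModelSpec
    reason: str
    elapsed_s: float


@dataclass
class FittedModel:
    """A trained classifier with its provenance and probability contract."""

    spec: ModelSpec
    best_params: dict
    estimator: object
    n_features: int
    cv_score: float | None = None
    train_digest: str = ""

    def _check_dims(self, X: FeatureMatrix) -> None:
        if X.d != self.n_features:
            raise ValueError(
                f"feature dimension mismatch: model expects d={self.n_features}, "
                f"got d={X.d}; train and test must share one preprocessing config"
            )

    def predict_proba(self, X: FeatureMatrix):
        """Per-instance class probabilities, columns ordered (bad, good)."""
        from printqc.metrics import ProbPredictions

        self._check_dims(X)
        raw = self.estimator.predict_proba(X.values)
        classes = list(self.estimator.classes_)
        cols = [classes.index(c) for c in CLASS_ORDER]
        return ProbPredictions(probs=raw[:, cols], actuals=X.labels)

    def predict_label(self, X: FeatureMatrix) -> np.ndarray:
        """Argmax label with ties resolved to 'bad' (conservative QC)."""
        probs = self.predict_proba(X).probs
        return np.where(probs[:, 1] > probs[:, 0], "good", "bad")


def make_estimator(technique: str, seed: int, **params):
    """Instantiate the scikit-learn estimator behind one technique."""
    if technique == "LR":
        # l1_ratio=0 is the ridge penalty (sklearn >= 1.8 deprecates penalty=)
        return LogisticRegression(l1_ratio=0, max_iter=200, random_state=seed, **params)
    if technique == "DT":
        return DecisionTreeClassifier(random_state=seed, **params)
    if technique == "RF":
        return RandomForestClassifier(random_state=seed, **params)
    if technique == "GB":
        return GradientBoostingClassifier(random_state=seed, **params)
    if technique == "MLP":
        return MLPClassifier(max_iter=150, random_state=seed, **params)
    if technique == "SVM":
        return SVC(kernel="rbf", probability=True, random_state=seed, **params)
    if technique == "kNN":
        return KNeighborsClassifier(**params)
    raise ValueError(f"unknown technique {technique!r}")


def _grid_candidates(grid: dict[str, list]) -> list[dict]:
    keys = list(grid.keys())
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def train(
    spec: ModelSpec,
    train_matrix: FeatureMatrix,
    budget: TrainBudget | None = None,
) -> FittedModel | ExceededLimits:
    """Fit one technique, grid-searched if the spec says tuned.

    Returns a FittedModel, or an ExceededLimits record when the cooperative
    budget runs out (never a crash). Deterministic under the spec seed.
    """
    labels = np.asarray(train_matrix.labels)
    present = set(labels.tolist())
    if len(present) < 2:
        raise ValueError(f"training data has a single class {present}; need both")

    t0 = time.monotonic()
    if budget and budget.max_features is not None and train_matrix.d > budget.max_features:
        return ExceededLimits(
            spec=spec,
            reason=f"d={train_matrix.d} exceeds max_features={budget.max_features}",
            elapsed_s=0.0,
        )

    X, y = train_matrix.values, labels
    best_params: dict = dict(spec.fixed_params)
    best_score: float | None = None

    if spec.tuned:
        cv = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
        for candidate in _grid_candidates(spec.resolved_grid()):
            if budget and budget.wall_time_s is not None:
                if time.monotonic() - t0 > budget.wall_time_s:
                    return ExceededLimits(
                        spec=spec,
                        reason=f"wall time budget {budget.wall_time_s}s exhausted "
                        "during grid search",
                        elapsed_s=time.monotonic() - t0,
                    )
            params = dict(spec.fixed_params, **candidate)
            est = make_estimator(spec.technique, spec.seed, **params)
            score = float(np.mean(cross_val_score(est, X, y, cv=cv, scoring="accuracy")))
            if best_score is None or score > best_score:  # strict: ties keep first
                best_score, best_params = score, params

    if budget and budget.wall_time_s is not None:
        if time.monotonic() - t0 > budget.wall_time_s:
            return ExceededLimits(
                spec=spec,
                reason=f"wall time budget {budget.wall_time_s}s exhausted before final fit",
                elapsed_s=time.monotonic() - t0,
            )

    estimator = make_estimator(spec.technique, spec.seed, **best_params)
    estimator.fit(X, y)
    digest = f"train:n={train_matrix.n}:d={train_matrix.d}:seed={spec.seed}"
    return FittedModel(
        spec=spec,
        best_params=best_params,
        estimator=estimator,
        n_features=train_matrix.d,
        cv_score=best_score,
        train_digest=digest,
    )


def cv_score_grid(spec: ModelSpec, train_matrix: FeatureMatrix) -> list[tuple[dict, float]]:
    """Mean CV accuracy of every grid candidate, in declared order.

    Exposed so the grid-search optimality contract can be verified
    exhaustively against the candidate list.
    """
    cv = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    out = []
    for candidate in _grid_candidates(spec.resolved_grid()):
        params = dict(spec.fixed_params, **candidate)
        est = make_estimator(spec.technique, spec.seed, **params)
        score = float(
            np.mean(
                cross_val_score(est, train_matrix.values, train_matrix.labels, cv=cv, scoring="accuracy")
            )
        )
        out.append((params, score))
    return out


def save_model(model: FittedModel, path) -> None:
    """Persist a fitted model as a joblib artifact plus a JSON sidecar
    describing technique, best params, feature size and class order."""
    import json
    from pathlib import Path

    import joblib

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    joblib.dump(model.estimator, path)
    sidecar = {
        "format_version": 1,
        "technique": model.spec.technique,
        "tuned": model.spec.tuned,
        "seed": model.spec.seed,
        "best_params": {k: repr(v) for k, v in model.best_params.items()},
        "n_features": model.n_features,
        "class_order": list(CLASS_ORDER),
        "cv_score": model.cv_score,
        "train_digest": model.train_digest,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path) -> FittedModel:
    """Load a model saved by save_model."""
    import json
    from pathlib import Path

    import joblib

    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    if sidecar.get("format_version") != 1:
        raise ValueError(f"unsupported model artifact version in {path}")
    estimator = joblib.load(path)
    spec = ModelSpec(
        technique=sidecar["technique"],
        tuned=sidecar["tuned"],
        seed=sidecar["seed"],
    )
    return FittedModel(
        spec=spec,
        best_params=dict(estimator.get_params()),
        estimator=estimator,
        n_features=sidecar["n_features"],
        cv_score=sidecar.get("cv_score"),
        train_digest=sidecar.get("train_digest", ""),
    )
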