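"""RBF-kernel SVM tile classifier with grid-searched hyperparameters.

Features are z-scored (zero-variance columns dropped and recorded), a
Gaussian-RBF support vector machine is selected by stratified 5-fold
cross-validated grid search over (C, γ), refit on all data, and Platt-style
sigmoid calibration (sklearn's built-in probability machinery) provides a
tumor posterior in [0, 1] per tile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import N_FEATURES, SCHEMA_VERSION

DEFAULT_GRID = {
    "svc__estimator__C": [0.1, 1.0, 10.0, 100.0],
    "svc__estimator__gamma": list(np.logspace(-3, 1, 5)),
}

LABEL_NONTUMOR = 0
LABEL_TUMOR = 1


@dataclass
class CVReport:
    """Full cross-validation grid with the selected point."""

    grid: list[dict]
    best_params: dict
    best_cv_accuracy: float
    folds: int
    n_samples: int
    n_per_class: dict[int, int]

    def to_dict(self) -> dict:
        return {
            "grid": self.grid,
            "best_params": self.best_params,
            "best_cv_accuracy": self.best_cv_accuracy,
            "folds": self.folds,
            "n_samples": self.n_samples,
            "n_per_class": {str(k): v for k, v in self.n_per_class.items()},
        }


@dataclass
class TrainedModel:
    """Fitted scaler+SVM pipeline plus the metadata needed at inference."""

    pipeline: Pipeline
    schema_version: str
    dropped_features: list[int]
    kept_features: np.ndarray
    meta: dict = field(default_factory=dict)
    decision_threshold: float = 0.5


@dataclass
class TileClassification:
    label: int  # LABEL_TUMOR / LABEL_NONTUMOR
    posterior: float  # P(tumor)


def train(
    X: np.ndarray,
    y: np.ndarray,
    grid: dict | None = None,
    folds: int = 5,
    seed: int = 0,
    decision_threshold: float = 0.5,
    class_weight: str | None = None,
) -> tuple[TrainedModel, CVReport]:
    """Fit the tile classifier by grid-searched stratified k-fold CV.

    ``y`` holds 0 (non-tumor) / 1 (tumor).  Raises on single-class input
    or fewer than ``folds`` samples in either class.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    if X.ndim != 2 or X.shape[1] != N_FEATURES:
        raise ValueError(f"expected (n, {N_FEATURES}) feature matrix, got {X.shape}")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("training data must contain both classes")
    if counts.min() < folds:
        raise ValueError(f"need at least {folds} samples per class for {folds}-fold CV")

    sd = X.std(axis=0)
    tol = 1e-12 * np.maximum(1.0, np.abs(X.mean(axis=0)))  # constant up to roundoff
    kept = np.flatnonzero(sd > tol)
    dropped = sorted(set(range(X.shape[1])) - set(kept.tolist()))
    Xk = X[:, kept]

    # Platt-style sigmoid posterior calibration fit on internal CV folds
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "svc",
                CalibratedClassifierCV(
                    SVC(kernel="rbf", random_state=seed, class_weight=class_weight),
                    method="sigmoid",
                    cv=min(5, int(counts.min())),
                    ensemble=False,
                ),
            ),
        ]
    )
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        pipe, grid or DEFAULT_GRID, cv=cv, scoring="accuracy", n_jobs=1, refit=True
    )
    search.fit(Xk, y)

    res = search.cv_results_
    grid_rows = [
        {"params": p, "mean_cv_accuracy": float(m), "std_cv_accuracy": float(s)}
        for p, m, s in zip(res["params"], res["mean_test_score"], res["std_test_score"])
    ]
    report = CVReport(
        grid=grid_rows,
        best_params={k: float(v) for k, v in search.best_params_.items()},
        best_cv_accuracy=float(search.best_score_),
        folds=folds,
        n_samples=int(len(y)),
        n_per_class={int(c): int(n) for c, n in zip(classes, counts)},
    )
    model = TrainedModel(
        pipeline=search.best_estimator_,
        schema_version=SCHEMA_VERSION,
        dropped_features=dropped,
        kept_features=kept,
        meta={
            "cv_accuracy": report.best_cv_accuracy,
            "best_params": report.best_params,
            "n_per_class": report.n_per_class,
            "seed": seed,
        },
        decision_threshold=decision_threshold,
    )
    return model, report


def classify_tiles(
    model: TrainedModel, X: np.ndarray, schema_version: str = SCHEMA_VERSION
) -> list[TileClassification]:
    """Label tiles and attach tumor posteriors; empty input → empty list."""
    if model.schema_version != schema_version:
        raise ValueError(
            f"feature schema mismatch: model '{model.schema_version}' "
            f"vs features '{schema_version}'"
        )
    X = np.asarray(X, float)
    if X.size == 0:
        return []
    if X.ndim != 2 or X.shape[1] != N_FEATURES:
        raise ValueError(f"expected (n, {N_FEATURES}) feature matrix, got {X.shape}")
    proba = model.pipeline.predict_proba(X[:, model.kept_features])
    tumor_col = list(model.pipeline.classes_).index(LABEL_TUMOR)
    post = np.clip(proba[:, tumor_col], 0.0, 1.0)
    return [
        TileClassification(
            label=LABEL_TUMOR if p >= model.decision_threshold else LABEL_NONTUMOR,
            posterior=float(p),
        )
        for p in post
    ]


def save_model(model: TrainedModel, path: str | Path) -> None:
    joblib.dump(model, path)


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    model = joblib.load(path)
    if not isinstance(model, TrainedModel):
        raise ValueError(f"{path} is not a hemark model file")
    return model
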