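"""Small-cyst texture classification.

Very small bright regions are ambiguous: renal tubules, bile ducts and
vessel lumens look like small cysts to the intensity pipeline.  A support
vector machine with an RBF kernel, fed the 54-dimensional LBP texture
descriptor, discriminates true small cysts (smooth lumens) from these false
positives.

Hyper-parameters (C, gamma) are chosen by grid search over powers of two,
scored by mean Cohen kappa under stratified 4-fold cross-validation on a
75% train+validation pool; the remaining held-out 25% yields the reported
test kappa and accuracy.  Ties prefer the smaller C, then the smaller gamma
(smoother models).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .raster import CystSet, as_grey_image
from .texture import LbpConfig, RegionUnsupportedError, compute_lbp_features

__all__ = [
    "TRUE_CYST",
    "FALSE_POSITIVE",
    "LabeledDataset",
    "GridSearchConfig",
    "TrainedClassifier",
    "cohen_kappa",
    "train_small_cyst_classifier",
    "classify_candidates",
    "save_classifier",
    "load_classifier",
]

TRUE_CYST = "true_cyst"
FALSE_POSITIVE = "false_positive"


@dataclass(frozen=True)
class LabeledDataset:
    """Feature matrix with per-sample labels and provenance tags."""

    features: np.ndarray
    labels: tuple
    provenance: tuple = ()

    def __post_init__(self):
        feats = np.asarray(self.features, dtype=np.float64)
        labels = tuple(self.labels)
        if feats.ndim != 2 or feats.shape[0] != len(labels):
            raise ValueError("features must be (n_samples, n_features) matching labels")
        for lab in labels:
            if lab not in (TRUE_CYST, FALSE_POSITIVE):
                raise ValueError(f"unknown label {lab!r}")
        prov = tuple(self.provenance) if self.provenance else ("",) * len(labels)
        if len(prov) != len(labels):
            raise ValueError("provenance length must match labels")
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "provenance", prov)

    def __len__(self):
        return len(self.labels)


@dataclass(frozen=True)
class GridSearchConfig:
    """Power-of-two grid for (C, gamma) and the CV schedule."""

    c_exponents: tuple = tuple(range(-5, 16, 2))
    gamma_exponents: tuple = tuple(range(-13, 4, 2))
    folds: int = 4
    seed: int = 0

    def __post_init__(self):
        if not self.c_exponents or not self.gamma_exponents:
            raise ValueError("grids must be non-empty")
        if self.folds < 2:
            raise ValueError("at least 2 CV folds required")


@dataclass(frozen=True)
class TrainedClassifier:
    """Fitted RBF-SVM with the selected (C, gamma) and its training report."""

    C: float
    gamma: float
    svc: SVC
    lbp_config: LbpConfig = field(default_factory=LbpConfig)
    report: dict = field(default_factory=dict)

    def predict(self, features: np.ndarray) -> np.ndarray:
        feats = np.atleast_2d(np.asarray(features, dtype=np.float64))
        return self.svc.predict(feats)


def cohen_kappa(confusion) -> float:
    """Cohen's chance-corrected agreement from a 2x2 confusion table.

    kappa = (p_o - p_e) / (1 - p_e); returns 0 when p_e = 1 (both raters
    constant and in agreement).
    """
    table = np.asarray(confusion, dtype=np.float64)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("confusion must be a 2x2 table of non-negative counts")
    n = table.sum()
    if n == 0:
        raise ValueError("empty confusion table")
    p_o = np.trace(table) / n
    p_e = float(np.sum(table.sum(axis=0) * table.sum(axis=1))) / (n * n)
    if p_e == 1.0:
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    table = np.zeros((2, 2), dtype=np.int64)
    for t, p in ((0, 0), (0, 1), (1, 0), (1, 1)):
        table[t, p] = int(np.sum((y_true == t) & (y_pred == p)))
    return table


def _kappa_score(y_true, y_pred) -> float:
    return cohen_kappa(_confusion(np.asarray(y_true), np.asarray(y_pred)))


def train_small_cyst_classifier(
    data: LabeledDataset, grid: GridSearchConfig = GridSearchConfig()
) -> TrainedClassifier:
    """Grid-searched RBF-SVM over a labelled feature set.

    The data is shuffled (seeded, stratified) into 75% train+validation and
    25% test.  Every (C, gamma) grid cell is scored by mean Cohen kappa over
    stratified k-fold CV on the pool; the winner (ties: smaller C, then
    smaller gamma) is refit on the whole pool and evaluated on the held-out
    test split.
    """
    y = np.array([1 if lab == TRUE_CYST else 0 for lab in data.labels])
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes to be present")
    if len(y) < 2 * grid.folds:
        raise ValueError(f"need at least {2 * grid.folds} samples for {grid.folds}-fold CV")
    x = data.features

    x_pool, x_test, y_pool, y_test = train_test_split(
        x, y, test_size=0.25, stratify=y, random_state=grid.seed
    )
    cv = StratifiedKFold(n_splits=grid.folds, shuffle=True, random_state=grid.seed)
    splits = list(cv.split(x_pool, y_pool))

    cv_table = {}
    best = None
    for ci in grid.c_exponents:
        for gi in grid.gamma_exponents:
            c_val, g_val = 2.0**ci, 2.0**gi
            fold_kappas = []
            for train_idx, val_idx in splits:
                svc = SVC(kernel="rbf", C=c_val, gamma=g_val)
                svc.fit(x_pool[train_idx], y_pool[train_idx])
                fold_kappas.append(_kappa_score(y_pool[val_idx], svc.predict(x_pool[val_idx])))
            mean_kappa = float(np.mean(fold_kappas))
            cv_table[(ci, gi)] = mean_kappa
            if best is None or mean_kappa > best[0]:
                best = (mean_kappa, ci, gi, fold_kappas)

    best_kappa, best_ci, best_gi, best_folds = best
    final = SVC(kernel="rbf", C=2.0**best_ci, gamma=2.0**best_gi)
    final.fit(x_pool, y_pool)
    y_pred = final.predict(x_test)
    report = {
        "cv_table": {f"{ci},{gi}": k for (ci, gi), k in cv_table.items()},
        "per_fold_kappa": [float(k) for k in best_folds],
        "cv_mean_kappa": best_kappa,
        "test_kappa": _kappa_score(y_test, y_pred),
        "test_accuracy": float(np.mean(y_pred == y_test)),
        "n_train_val": int(len(y_pool)),
        "n_test": int(len(y_test)),
        "seed": grid.seed,
    }
    return TrainedClassifier(C=2.0**best_ci, gamma=2.0**best_gi, svc=final, report=report)


def classify_candidates(
    candidates: CystSet, grey: np.ndarray, model: TrainedClassifier
) -> tuple[CystSet, CystSet]:
    """Partition candidate cysts into (accepted, rejected) by texture.

    Candidates whose region cannot support the LBP neighbourhood are routed
    to the rejected set.
    """
    if not isinstance(model, TrainedClassifier):
        raise TypeError("model must be a TrainedClassifier")
    grey = as_grey_image(grey)
    accepted, rejected = [], []
    for cyst in candidates:
        try:
            feats = compute_lbp_features(grey, cyst, model.lbp_config)
        except RegionUnsupportedError:
            rejected.append(cyst)
            continue
        if int(model.predict(feats)[0]) == 1:
            accepted.append(cyst)
        else:
            rejected.append(cyst)
    return candidates.with_cysts(accepted), candidates.with_cysts(rejected)


_FORMAT_VERSION = 1


def save_classifier(model: TrainedClassifier, path) -> None:
    """Persist a trained classifier as a versioned archive."""
    joblib.dump(
        {
            "format_version": _FORMAT_VERSION,
            "C": model.C,
            "gamma": model.gamma,
            "svc": model.svc,
            "lbp_scales": model.lbp_config.scales,
            "report": model.report,
        },
        path,
    )


def load_classifier(path) -> TrainedClassifier:
    blob = joblib.load(path)
    if blob.get("format_version") != _FORMAT_VERSION:
        raise ValueError("unsupported classifier archive version")
    return TrainedClassifier(
        C=blob["C"],
        gamma=blob["gamma"],
        svc=blob["svc"],
        lbp_config=LbpConfig(tuple(map(tuple, blob["lbp_scales"]))),
        report=blob["report"],
    )
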