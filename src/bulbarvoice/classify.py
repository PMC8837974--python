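"""Cross-validated evaluation of the five supervised models.

Per comparison and sex: stratified 10-fold cross-validation; inside each
fold the scaler is fitted on the training rows only, the minority class is
upsampled with replacement to equality (training rows only), all five model
families (SVM, NN, LDA, LR, RF) are trained, and held-out rows are scored
at the 50% probability threshold.  Metrics are pooled confusion counts over
folds, reported as accuracy / sensitivity / specificity in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .selection import Comparison

__all__ = [
    "MODEL_NAMES",
    "CVConfig",
    "CVReport",
    "build_models",
    "upsample_training",
    "confusion_metrics",
    "run_cv",
]

MODEL_NAMES = ("SVM", "NN", "LDA", "LR", "RF")


@dataclass
class CVConfig:
    n_folds: int = 10
    threshold: float = 0.5
    upsample: bool = True
    seed: int = 0
    group_by_subject: bool = False


@dataclass
class CVReport:
    comparison: Comparison
    metrics: dict = field(default_factory=dict)   # model -> {accuracy, sensitivity, specificity}
    counts: dict = field(default_factory=dict)    # model -> {tp, fn, tn, fp}
    fold_counts: dict = field(default_factory=dict)  # model -> list of per-fold dicts
    config: CVConfig = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for model in MODEL_NAMES:
            for metric in ("accuracy", "sensitivity", "specificity"):
                rows.append(dict(
                    comparison=self.comparison.name, sex=self.comparison.sex,
                    model=model, metric=metric,
                    value=round(self.metrics[model][metric], 1),
                ))
        return pd.DataFrame(rows)


def build_models(seed: int = 0) -> dict:
    """The five model families with fixed, paper-era default hyperparameters."""
    return {
        # sigmoid-calibrated decision scores stand in for SVC probabilities
        "SVM": CalibratedClassifierCV(
            SVC(kernel="rbf", C=1.0, gamma="scale"), method="sigmoid",
            cv=3, ensemble=False),
        "NN": MLPClassifier(hidden_layer_sizes=(10,), max_iter=3000,
                            random_state=seed),
        "LDA": LinearDiscriminantAnalysis(),
        "LR": LogisticRegression(C=1.0, max_iter=5000),
        "RF": RandomForestClassifier(n_estimators=500, random_state=seed),
    }


def upsample_training(
    x: np.ndarray, y: np.ndarray, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Resample the minority class with replacement until class counts match."""
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("upsampling requires two classes in the training data")
    if counts[0] == counts[1]:
        return x, y
    rng = np.random.default_rng(seed)
    minority = classes[np.argmin(counts)]
    need = int(abs(counts[0] - counts[1]))
    idx = np.flatnonzero(y == minority)
    extra = rng.choice(idx, size=need, replace=True)
    order = np.concatenate([np.arange(len(y)), extra])
    return x[order], y[order]


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) in percent from confusion counts."""
    if min(tp, fn, tn, fp) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("cannot compute metrics with an empty class")
    total = tp + fn + tn + fp
    return (
        100.0 * (tp + tn) / total,
        100.0 * tp / (tp + fn),
        100.0 * tn / (tn + fp),
    )


def run_cv(
    table: pd.DataFrame,
    selected: list,
    cmp: Comparison,
    cfg: CVConfig | None = None,
) -> CVReport:
    """Stratified k-fold CV of all five models on the selected features."""
    cfg = cfg or CVConfig()
    if not selected:
        raise ValueError("no features selected")
    sub = table[table["sex"] == cmp.sex] if "sex" in table.columns else table
    side = cmp.labels(sub["group"])
    sub = sub[side.notna()].copy()
    sub["_y"] = (side[side.notna()] == cmp.positive).astype(int)
    sub = sub.dropna(subset=selected)

    x = sub[selected].to_numpy(dtype=np.float64)
    y = sub["_y"].to_numpy()
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if min(n_pos, n_neg) < cfg.n_folds:
        raise ValueError(
            f"{cmp.name}/{cmp.sex}: need >= {cfg.n_folds} observations per class, "
            f"got {n_pos} positive / {n_neg} negative"
        )

    if cfg.group_by_subject:
        splitter = StratifiedGroupKFold(n_splits=cfg.n_folds, shuffle=True,
                                        random_state=cfg.seed)
        splits = splitter.split(x, y, groups=sub["subject_id"])
    else:
        splitter = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True,
                                   random_state=cfg.seed)
        splits = splitter.split(x, y)

    counts = {m: dict(tp=0, fn=0, tn=0, fp=0) for m in MODEL_NAMES}
    fold_counts = {m: [] for m in MODEL_NAMES}
    for fold, (tr, te) in enumerate(splits):
        scaler = StandardScaler().fit(x[tr])
        x_tr, y_tr = scaler.transform(x[tr]), y[tr]
        x_te, y_te = scaler.transform(x[te]), y[te]
        if cfg.upsample:
            x_tr, y_tr = upsample_training(x_tr, y_tr, seed=cfg.seed + fold)
        models = build_models(seed=cfg.seed)
        for name, model in models.items():
            model.fit(x_tr, y_tr)
            proba = model.predict_proba(x_te)[:, list(model.classes_).index(1)]
            pred = (proba >= cfg.threshold).astype(int)
            fc = dict(
                tp=int(((pred == 1) & (y_te == 1)).sum()),
                fn=int(((pred == 0) & (y_te == 1)).sum()),
                tn=int(((pred == 0) & (y_te == 0)).sum()),
                fp=int(((pred == 1) & (y_te == 0)).sum()),
            )
            fold_counts[name].append(fc)
            for k in fc:
                counts[name][k] += fc[k]

    metrics = {}
    for name in MODEL_NAMES:
        acc, sens, spec = confusion_metrics(**counts[name])
        metrics[name] = dict(accuracy=acc, sensitivity=sens, specificity=spec)
    return CVReport(comparison=cmp, metrics=metrics, counts=counts,
                    fold_counts=fold_counts, config=cfg)
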