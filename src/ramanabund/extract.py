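"""Growth-stage classification and characteristic-peak extraction.

A gradient-boosted decision-tree ensemble (second-order boosting objective
with l1+l2 regularization) is trained on preprocessed per-channel intensities
to recognize the culture time or growth phase of each cell.  Hyperparameters
are chosen by grid search with stratified 3-fold cross-validation on the 80%
training split; the report (confusion matrix, per-class and mean accuracy,
one-vs-rest ROC/AUC) is computed on the held-out 20%.

Characteristic peaks are the wavenumber channels with the highest total split
gain in the trained ensemble; near-duplicate channels are collapsed and
channels without a protein / nucleic-acid assignment are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import auc, confusion_matrix, roc_curve, silhouette_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from xgboost import XGBClassifier

from .config import DEFAULT_ASSIGNMENTS, PipelineConfig
from .io import SpectrumSet


class StratificationError(ValueError):
    pass


class EmbeddingError(ValueError):
    pass


@dataclass
class ClassifierReport:
    classes: list
    confusion: np.ndarray
    accuracy: float
    per_class_accuracy: dict
    best_params: dict
    roc: dict = field(default_factory=dict)  # class -> (fpr, tpr)
    auc: dict = field(default_factory=dict)  # class -> float
    cv_folds: int = 3
    test_fraction: float = 0.2


@dataclass
class GainRanking:
    """(wavenumber, total gain) pairs, gain non-increasing, ties to lower wavenumber."""

    entries: list[tuple[float, float]]

    def top(self, k: int) -> list[tuple[float, float]]:
        return self.entries[:k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["wavenumber_cm1", "gain"])


@dataclass
class AssignmentTable:
    """Band-center -> biomolecule class lookup with a +- tolerance."""

    assignments: dict[float, str] = field(default_factory=lambda: dict(DEFAULT_ASSIGNMENTS))
    tolerance: float = 2.0

    def lookup(self, wavenumber: float) -> str | None:
        best, best_d = None, None
        for center, cls in self.assignments.items():
            d = abs(wavenumber - center)
            if d <= self.tolerance and (best_d is None or d < best_d):
                best, best_d = cls, d
        return best


# ---------------------------------------------------------------------------
# embedding


def embed_pca_lda(sset: SpectrumSet, variance_keep: float = 0.95,
                  label_column: str = "phase") -> tuple[np.ndarray, float]:
    """PCA to ``variance_keep`` cumulative variance, then a 2-D supervised
    linear-discriminant projection; returns (embedding, silhouette)."""
    labels = sset.labels[label_column].to_numpy()
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise EmbeddingError("LDA needs at least two classes")
    if counts.min() < 2:
        raise EmbeddingError("every class needs >= 2 spectra")
    Z = PCA(n_components=variance_keep, svd_solver="full").fit_transform(sset.intensities)
    n_axes = min(2, classes.size - 1, Z.shape[1])
    E = LinearDiscriminantAnalysis(n_components=n_axes).fit_transform(Z, labels)
    sil = float(silhouette_score(E, labels, metric="euclidean"))
    return E, sil


# ---------------------------------------------------------------------------
# classifier


def _label_vector(sset: SpectrumSet, label_mode: str) -> np.ndarray:
    if label_mode == "phase":
        return sset.labels["phase"].to_numpy()
    if label_mode == "culture_time":
        return sset.labels["culture_time_h"].to_numpy()
    raise ValueError(f"label_mode must be 'phase' or 'culture_time', got {label_mode!r}")


def _make_xgb(seed: int, **params) -> XGBClassifier:
    return XGBClassifier(
        tree_method="hist", max_bin=32, n_jobs=1, random_state=seed,
        verbosity=0, **params)


def train_growth_classifier(sset: SpectrumSet, label_mode: str = "phase",
                            grid: dict | None = None,
                            seed: int = 42,
                            config: PipelineConfig | None = None,
                            ) -> tuple[XGBClassifier, ClassifierReport]:
    """Grid-searched boosted-tree classifier with a held-out stratified test split.

    Returns the refit best model (trained on the full 80% training split) and
    a report evaluated on the 20% test split, including one-vs-rest ROC/AUC.
    """
    cfg = config or PipelineConfig()
    if grid is None:
        grid = {
            "n_estimators": list(cfg.grid_n_estimators),
            "max_depth": list(cfg.grid_max_depth),
            "learning_rate": list(cfg.grid_learning_rate),
        }
    raw = _label_vector(sset, label_mode)
    classes, y = np.unique(raw, return_inverse=True)
    counts = np.bincount(y)
    if counts.min() < 3:
        raise StratificationError(
            f"class {classes[np.argmin(counts)]!r} has fewer than 3 members")
    X = sset.intensities.astype(np.float32)
    Xtr, Xte, ytr, yte = train_test_split(
        X, y, test_size=cfg.test_fraction, stratify=y, random_state=seed)
    cv = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(_make_xgb(seed), grid, cv=cv, n_jobs=1, refit=True)
    search.fit(Xtr, ytr)
    model = search.best_estimator_

    pred = model.predict(Xte)
    cm = confusion_matrix(yte, pred, labels=np.arange(classes.size))
    acc = float((pred == yte).mean())
    per_class = {
        str(classes[k]): float(cm[k, k] / cm[k].sum()) if cm[k].sum() else float("nan")
        for k in range(classes.size)
    }
    report = ClassifierReport(
        classes=[c.item() if hasattr(c, "item") else c for c in classes],
        confusion=cm, accuracy=acc, per_class_accuracy=per_class,
        best_params=dict(search.best_params_),
        cv_folds=cfg.cv_folds, test_fraction=cfg.test_fraction)
    report.roc, report.auc = compute_roc(model, Xte, yte, report.classes)
    # remember the split for downstream use (gain ranking uses the model as-is)
    model._ramanabund_classes = report.classes  # type: ignore[attr-defined]
    return model, report


def compute_roc(model, X_test: np.ndarray, y_test: np.ndarray,
                classes: list) -> tuple[dict, dict]:
    """One-vs-rest ROC curves and trapezoidal AUC per class on a test split."""
    present = np.unique(y_test)
    scores = model.predict_proba(X_test)
    rocs, aucs = {}, {}
    for k, cls in enumerate(classes):
        if k not in present:
            raise StratificationError(f"class {cls!r} absent from the test split")
        fpr, tpr, _ = roc_curve((y_test == k).astype(int), scores[:, k])
        rocs[cls] = (fpr, tpr)
        aucs[cls] = float(auc(fpr, tpr))
    return rocs, aucs


# ---------------------------------------------------------------------------
# gain ranking and peak selection


def rank_gain(model: XGBClassifier, wavenumbers: np.ndarray,
              mode: str = "total") -> GainRanking:
    """Per-channel split gain summed over the ensemble, descending.

    ``mode='total'`` ranks by total gain (sum of loss reduction over all
    splits on the channel); ``mode='average'`` by gain per split.
    """
    importance = {"total": "total_gain", "average": "gain"}.get(mode)
    if importance is None:
        raise ValueError("mode must be 'total' or 'average'")
    booster = model.get_booster()
    raw = booster.get_score(importance_type=importance)
    pairs = []
    for feat, g in raw.items():
        idx = int(feat[1:]) if feat.startswith("f") else int(feat)
        pairs.append((float(wavenumbers[idx]), float(g)))
    pairs.sort(key=lambda t: (-t[1], t[0]))
    return GainRanking(pairs)


def select_characteristic_peaks(ranking: GainRanking,
                                table: AssignmentTable | None = None,
                                top_k: int = 20,
                                dedupe_window: float = 4.0,
                                ) -> list[tuple[float, str, float]]:
    """Top-gain channels -> deduplicated, assignment-filtered peak list.

    Channels within ``dedupe_window`` cm^-1 of a higher-gain channel are
    collapsed onto it; channels assigned ``excluded`` or without an assignment
    are dropped.  Returns (wavenumber, biomolecule, gain) sorted by gain.
    """
    tab = table or AssignmentTable()
    kept: list[tuple[float, float]] = []
    for wn, gain in ranking.top(top_k):
        if any(abs(wn - w0) <= dedupe_window for w0, _ in kept):
            continue
        kept.append((wn, gain))
    out = []
    for wn, gain in kept:
        cls = tab.lookup(wn)
        if cls is None or cls == "excluded":
            continue
        out.append((wn, cls, gain))
    out.sort(key=lambda t: (-t[2], t[0]))
    return out


def ranking_frame(ranking: GainRanking, table: AssignmentTable | None = None,
                  top_k: int = 20, dedupe_window: float = 4.0) -> pd.DataFrame:
    """Audit table: rank, wavenumber, gain, assignment, kept flag + drop reason."""
    tab = table or AssignmentTable()
    selected = {wn for wn, _, _ in
                select_characteristic_peaks(ranking, tab, top_k, dedupe_window)}
    rows = []
    for rank, (wn, gain) in enumerate(ranking.top(top_k), start=1):
        cls = tab.lookup(wn)
        if wn in selected:
            kept, reason = True, ""
        elif cls == "excluded":
            kept, reason = False, "excluded assignment"
        elif cls is None:
            kept, reason = False, "unassigned"
        else:
            kept, reason = False, "duplicate of higher-gain channel"
        rows.append({"rank": rank, "wavenumber_cm1": wn, "gain": gain,
                     "assignment": cls or "", "kept": kept, "drop_reason": reason})
    return pd.DataFrame(rows)
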