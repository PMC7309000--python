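"""Labeling rules, classification, and the leak-free nested protocol.

Trials are scored by stratified k-fold (default five-fold) cross-validation.
Inside each fold, feature normalization statistics and the selected-feature
mask are fitted on the training folds only and then frozen before the test
fold is touched, so reported accuracies carry no selection leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .preprocessing import normalize_features
from .pso import PSOConfig, select_features, relief_select

__all__ = [
    "LabelRule",
    "assign_labels",
    "QUADRANT_NAMES",
    "train_classifier",
    "predict",
    "SelectorSpec",
    "EvaluationReport",
    "nested_crossval",
    "compare_selectors",
]

#: Quadrant class codes: 1=HAHV, 2=HALV, 3=LAHV, 4=LALV
#: (High/Low Arousal x High/Low Valence, threshold 5 with >= on the High side).
QUADRANT_NAMES = {1: "HAHV", 2: "HALV", 3: "LAHV", 4: "LALV"}


@dataclass(frozen=True)
class LabelRule:
    """Maps (valence, arousal) ratings to integer classes."""

    scheme: str = "quadrant"   # "quadrant" or "binary"
    threshold: float = 5.0

    def __post_init__(self) -> None:
        if self.scheme not in ("quadrant", "binary"):
            raise ValueError(f"unknown label scheme {self.scheme!r}")


def assign_labels(ratings: np.ndarray, rule: LabelRule) -> np.ndarray:
    """Threshold ratings into classes.

    ``ratings`` is ``trials x 2`` (valence, arousal) on the 1-9 scale.  The
    quadrant scheme yields 1=HAHV, 2=HALV, 3=LAHV, 4=LALV; values exactly at
    the threshold count as High.  The binary scheme thresholds valence:
    positive (>= threshold) -> +1, negative -> -1.
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2 or ratings.shape[1] < 2:
        raise ValueError("ratings must be trials x (valence, arousal)")
    valence, arousal = ratings[:, 0], ratings[:, 1]
    thr = rule.threshold
    if rule.scheme == "binary":
        return np.where(valence >= thr, 1, -1)
    high_a = arousal >= thr
    high_v = valence >= thr
    labels = np.empty(ratings.shape[0], dtype=int)
    labels[high_a & high_v] = 1
    labels[high_a & ~high_v] = 2
    labels[~high_a & high_v] = 3
    labels[~high_a & ~high_v] = 4
    return labels


def train_classifier(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> SVC:
    """Linear-kernel soft-margin SVM (C=1, one-vs-one for multiclass)."""
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    clf = SVC(kernel="linear", C=C, decision_function_shape="ovo")
    clf.fit(np.asarray(X, dtype=float), y)
    return clf


def predict(model: SVC, X: np.ndarray) -> np.ndarray:
    return model.predict(np.asarray(X, dtype=float))


@dataclass
class SelectorSpec:
    """Which feature selector to run inside each training fold.

    ``kind`` is one of ``none``, ``relief``, or ``pso``; for ``pso`` the
    ``strategy`` names the inertia schedule (``w0`` = LDW baseline,
    ``w1``..``w6`` = MLDW, ``constant``).
    """

    kind: str = "pso"
    strategy: str = "w6"
    keep_fraction: float = 0.5       # relief only
    pso: PSOConfig | None = None     # overrides; seed is re-derived per fold

    def __post_init__(self) -> None:
        if self.kind not in ("none", "relief", "pso"):
            raise ValueError(f"unknown selector kind {self.kind!r}")


def _run_selector(
    spec: SelectorSpec, X: np.ndarray, y: np.ndarray, seed: int
) -> np.ndarray:
    if spec.kind == "none":
        return np.ones(X.shape[1], dtype=bool)
    if spec.kind == "relief":
        return relief_select(X, y, spec.keep_fraction)
    base = spec.pso or PSOConfig(schedule=spec.strategy)
    cfg = PSOConfig(
        n_particles=base.n_particles,
        c1=base.c1,
        c2=base.c2,
        theta=base.theta,
        tmax=base.tmax,
        schedule=spec.strategy if spec.pso is None else base.schedule,
        velocity_clamp=base.velocity_clamp,
        init_low=base.init_low,
        init_high=base.init_high,
        init_velocity=base.init_velocity,
        seed=seed,
        inner_folds=base.inner_folds,
        svm_c=base.svm_c,
    )
    return select_features(X, y, cfg).mask


@dataclass
class EvaluationReport:
    """Per-fold accuracies, masks, confusion matrix and reproducibility info."""

    fold_accuracies: list[float]
    masks: list[np.ndarray]
    confusion: np.ndarray
    classes: list[int]
    seed: int
    config: dict = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies))

    def to_dict(self) -> dict:
        return {
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "mean_accuracy": self.mean_accuracy,
            "std_accuracy": self.std_accuracy,
            "masks": [m.astype(int).tolist() for m in self.masks],
            "confusion": self.confusion.tolist(),
            "classes": list(map(int, self.classes)),
            "seed": self.seed,
            "config": dict(self.config),
        }


def _resolve_features(trials_or_features, labels):
    """Accept a TrialSet (features extracted with defaults), a FeatureMatrix,
    or a plain array."""
    from .data import TrialSet
    from .features import extract_all

    if isinstance(trials_or_features, TrialSet):
        ts = trials_or_features
        if labels is None:
            labels = ts.labels
        return extract_all(ts).values, np.asarray(labels)
    X = (
        trials_or_features.values
        if hasattr(trials_or_features, "values")
        else np.asarray(trials_or_features, dtype=float)
    )
    return X, np.asarray(labels)


def nested_crossval(
    trials_or_features,
    labels: np.ndarray | None = None,
    selector: SelectorSpec | None = None,
    k: int = 5,
    seed: int = 0,
) -> EvaluationReport:
    """Stratified k-fold accuracy with in-fold selection.

    Per fold: z-score normalization is fitted on the training portion, the
    selector runs on normalized training data only, a linear SVM is fitted
    on the masked training columns, and the held-out fold is scored with the
    frozen statistics and mask.
    """
    selector = selector or SelectorSpec()
    X, y = _resolve_features(trials_or_features, labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"stratified {k}-fold needs >= {k} trials per class "
            f"(smallest class has {counts.min()})"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_acc: list[float] = []
    masks: list[np.ndarray] = []
    y_true_all: list[np.ndarray] = []
    y_pred_all: list[np.ndarray] = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        Xtr, stats = normalize_features(X[tr])
        mask = _run_selector(selector, Xtr, y[tr], seed=(seed * 1009 + fold) % (2 ** 31))
        clf = train_classifier(Xtr[:, mask], y[tr])
        Xte, _ = normalize_features(X[te], stats=stats)
        pred = predict(clf, Xte[:, mask])
        fold_acc.append(float((pred == y[te]).mean()))
        masks.append(mask)
        y_true_all.append(y[te])
        y_pred_all.append(pred)
    conf = confusion_matrix(
        np.concatenate(y_true_all), np.concatenate(y_pred_all), labels=classes
    )
    return EvaluationReport(
        fold_accuracies=fold_acc,
        masks=masks,
        confusion=conf,
        classes=list(classes),
        seed=seed,
        config={
            "k": k,
            "selector": selector.kind,
            "strategy": selector.strategy if selector.kind == "pso" else None,
        },
    )


def compare_selectors(
    trials_or_features,
    labels: np.ndarray | None = None,
    strategies: Sequence[str] = ("w0", "w2", "w6"),
    budgets: Sequence[int] = (10, 30, 50),
    seeds: Sequence[int] = (0,),
    k: int = 5,
    pso: PSOConfig | None = None,
):
    """Mean accuracy per strategy at several iteration budgets.

    For swarm strategies a single run per fold with ``tmax = max(budgets)``
    is performed and the global-best mask is snapshotted at each budget, so
    budgets are directly comparable on identical random streams.  The
    ``relief`` and ``none`` strategies are budget-independent and repeat
    their value across columns.  Returns a pandas DataFrame (rows:
    strategies, columns: budgets) of accuracies averaged over seeds and
    folds, plus a matching sd table, as attribute ``attrs['std']``.
    """
    import pandas as pd

    X, y = _resolve_features(trials_or_features, labels)
    budgets = sorted(budgets)
    table = np.zeros((len(strategies), len(budgets)))
    spread = np.zeros_like(table)
    for si, strat in enumerate(strategies):
        per_budget: dict[int, list[float]] = {b: [] for b in budgets}
        for seed in seeds:
            skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
            for fold, (tr, te) in enumerate(skf.split(X, y)):
                Xtr, stats = normalize_features(X[tr])
                Xte, _ = normalize_features(X[te], stats=stats)
                fold_seed = (seed * 1009 + fold) % (2 ** 31)
                if strat in ("none", "relief"):
                    if strat == "none":
                        mask = np.ones(X.shape[1], dtype=bool)
                    else:
                        mask = relief_select(Xtr, y[tr])
                    budget_masks = {b: mask for b in budgets}
                else:
                    base = pso or PSOConfig()
                    cfg = PSOConfig(
                        n_particles=base.n_particles,
                        theta=base.theta,
                        tmax=max(budgets),
                        schedule=strat,
                        seed=fold_seed,
                        inner_folds=base.inner_folds,
                        velocity_clamp=base.velocity_clamp,
                    )
                    res = select_features(
                        Xtr, y[tr], cfg, snapshot_at=tuple(budgets)
                    )
                    from .pso import decode_mask

                    budget_masks = {
                        b: decode_mask(res.gbest_snapshots[b], cfg.theta)
                        for b in budgets
                    }
                for b in budgets:
                    m = budget_masks[b]
                    clf = train_classifier(Xtr[:, m], y[tr])
                    acc = float((predict(clf, Xte[:, m]) == y[te]).mean())
                    per_budget[b].append(acc)
        for bi, b in enumerate(budgets):
            table[si, bi] = np.mean(per_budget[b])
            spread[si, bi] = np.std(per_budget[b])
    df = pd.DataFrame(table, index=list(strategies), columns=list(budgets))
    df.attrs["std"] = pd.DataFrame(
        spread, index=list(strategies), columns=list(budgets)
    )
    return df
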