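"""Per-subject fatigue classification: RFE feature selection, random-forest
models, stratified k-fold validation and report aggregation.

The modelling workflow follows the user-tuned design: one model per subject.
``SubjectFatigueModel`` wraps a subject's windows-by-features matrix; its
``fit`` runs a stratified 10-fold procedure in which, within every fold,
recursive feature elimination (step 1, internal stratified 5-fold accuracy
scored on the training split only) picks a feature subset, a 10-tree random
forest is trained on it, and the held-out windows are scored.  Predictions
are pooled over all folds before computing the confusion counts, accuracy /
precision / recall / F1 (in percent, positive class = cognitive fatigue) and
AUC-ROC from the pooled tree-vote fractions.  ``aggregate_report`` collects
per-subject results into a cohort table with mean +- population SD rows and
the subset mean over subjects exceeding 70% accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from ._forest import RandomForest
from .recording import FeatureMatrix, warn_degenerate

METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "auc_roc")


class FoldError(ValueError):
    """The requested cross-validation layout is infeasible for the data."""


@dataclass(frozen=True)
class ClassifierSpec:
    """Random-forest configuration.

    10 trees, sqrt(p) candidate features per node split, Gini criterion and
    a minimum of 2 samples to split a node; ``random_seed`` drives every
    stochastic component (bootstrap, feature subsets, fold shuffling)
    through a deterministic seed stream.
    """

    n_trees: int = 10
    max_features_rule: str = "sqrt"
    split_criterion: str = "gini"
    min_samples_split: int = 2
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.min_samples_split < 2:
            raise ValueError("min_samples_split must be >= 2")
        if self.max_features_rule != "sqrt":
            raise ValueError("only the sqrt feature rule is supported")
        if self.split_criterion != "gini":
            raise ValueError("only the Gini criterion is supported")


@dataclass(frozen=True)
class ConfusionCounts:
    """Pooled confusion counts; positive class = cognitive fatigue (1)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(np.sum((y_pred == 1) & (y_true == 1))),
            tn=int(np.sum((y_pred == 0) & (y_true == 0))),
            fp=int(np.sum((y_pred == 1) & (y_true == 0))),
            fn=int(np.sum((y_pred == 0) & (y_true == 1))),
        )

    def as_matrix(self) -> np.ndarray:
        """2x2 matrix [[tn, fp], [fn, tp]] (rows: true class 0/1)."""
        return np.array([[self.tn, self.fp], [self.fn, self.tp]])


def compute_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, recall and F1 in percent.

    Degenerate denominators (e.g. no positive prediction at all) yield 0
    with a warning rather than an error: with folds holding only a couple of
    windows these cases are reachable.
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics for zero samples")
    accuracy = 100.0 * (c.tp + c.tn) / c.total
    if c.tp + c.fp == 0:
        warn_degenerate("precision undefined (no positive predictions); returning 0")
        precision = 0.0
    else:
        precision = 100.0 * c.tp / (c.tp + c.fp)
    if c.tp + c.fn == 0:
        warn_degenerate("recall undefined (no positive samples); returning 0")
        recall = 0.0
    else:
        recall = 100.0 * c.tp / (c.tp + c.fn)
    if precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return {"accuracy": accuracy, "precision": precision, "recall": recall, "f1": f1}


def _seed_stream(master_seed: int):
    """Deterministic stream of sub-seeds (< 2**31) from one master seed."""
    rng = np.random.default_rng(np.random.SeedSequence(master_seed))
    while True:
        yield int(rng.integers(0, 2**31))


def _rfe_elimination_path(X, y, spec: ClassifierSpec, seeds) -> list[int]:
    """Eliminate the least-important feature one at a time.

    Returns column indices in elimination order (first eliminated first);
    the last entry is the single most persistent feature.  Importances are
    impurity-based, from the same forest family as the final classifier.
    """
    active = list(range(X.shape[1]))
    order: list[int] = []
    while len(active) > 1:
        rf = RandomForest(spec.n_trees, spec.min_samples_split, next(seeds))
        rf.fit(X[:, active], y)
        worst = int(np.argmin(rf.feature_importances_))
        order.append(active.pop(worst))
    order.append(active[0])
    return order


def _rfe_scored_path(Xtr, ytr, Xte, yte, spec, seeds) -> np.ndarray:
    """Held-out accuracy for every feature count along one elimination path.

    ``scores[c - 1]`` is the accuracy using the ``c`` surviving features.
    """
    p = Xtr.shape[1]
    scores = np.empty(p)
    active = list(range(p))
    while active:
        rf = RandomForest(spec.n_trees, spec.min_samples_split, next(seeds))
        rf.fit(Xtr[:, active], ytr)
        scores[len(active) - 1] = float(
            np.mean((rf.vote_fractions(Xte[:, active]) > 0.5).astype(int) == yte)
        )
        if len(active) == 1:
            break
        worst = int(np.argmin(rf.feature_importances_))
        active.pop(worst)
    return scores


def rfe_select(
    train: FeatureMatrix,
    spec: ClassifierSpec = ClassifierSpec(),
    seed: int | None = None,
    n_internal_folds: int = 5,
) -> tuple[tuple[str, ...], np.ndarray]:
    """Recursive feature elimination with internal cross-validated sizing.

    Every candidate feature count (156 down to 1, step 1) is scored by
    stratified ``n_internal_folds``-fold accuracy computed on the training
    matrix only; the best-scoring count wins, ties going to the smaller
    count.  A final elimination pass over the whole training matrix then
    yields the selected feature set of that size.

    Returns ``(selected_names, boolean_support_mask)``.
    """
    X, y = train.values, train.labels
    class_counts = np.bincount(y, minlength=2)
    if class_counts.min() < 2:
        raise FoldError("rfe_select needs at least 2 samples of each class")
    seeds = _seed_stream(spec.random_seed if seed is None else seed)

    k = int(min(n_internal_folds, class_counts.min()))
    if k < n_internal_folds:
        warn_degenerate(
            f"internal CV reduced to {k} folds (smallest class has "
            f"{class_counts.min()} samples)"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=next(seeds))
    fold_scores = [
        _rfe_scored_path(X[tr], y[tr], X[te], y[te], spec, seeds)
        for tr, te in skf.split(X, y)
    ]
    mean_scores = np.mean(fold_scores, axis=0)
    best_count = int(np.argmax(mean_scores)) + 1  # ties -> fewer features

    path = _rfe_elimination_path(X, y, spec, seeds)
    keep = path[len(path) - best_count :]
    support = np.zeros(X.shape[1], dtype=bool)
    support[keep] = True
    names = tuple(n for n, s in zip(train.feature_names, support) if s)
    return names, support


@dataclass
class SubjectFatigueResults:
    """Pooled cross-validated performance of one subject's model."""

    subject_id: str
    counts: ConfusionCounts
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc_roc: float
    selected_features: tuple[tuple[str, ...], ...]  # per fold
    fold_test_sizes: tuple[int, ...]
    y_true: np.ndarray
    y_pred: np.ndarray
    y_score: np.ndarray
    spec: ClassifierSpec = field(default_factory=ClassifierSpec)
    n_folds: int = 10

    def metrics(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc_roc": self.auc_roc,
        }

    def to_row(self) -> dict[str, float | str]:
        return {"subject": self.subject_id, **{k: round(v, 2) for k, v in self.metrics().items()}}

    def summary(self) -> str:
        c = self.counts
        lines = [
            f"Cognitive-fatigue classification -- subject {self.subject_id}",
            f"  windows: {c.total} ({self.n_folds}-fold stratified CV, pooled)",
            f"  confusion  TP={c.tp} TN={c.tn} FP={c.fp} FN={c.fn}",
            f"  accuracy   {self.accuracy:6.2f} %",
            f"  precision  {self.precision:6.2f} %",
            f"  recall     {self.recall:6.2f} %",
            f"  F1-score   {self.f1:6.2f} %",
            f"  AUC-ROC    {self.auc_roc:6.2f} %",
            f"  selected features/fold: "
            + ", ".join(str(len(s)) for s in self.selected_features),
        ]
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        """ROC curve from the pooled vote-fraction scores."""
        from sklearn.metrics import roc_curve

        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        fpr, tpr, _ = roc_curve(self.y_true, self.y_score)
        ax.plot(fpr, tpr, drawstyle="steps-post", label=f"AUC = {self.auc_roc:.1f} %")
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.set_title(f"subject {self.subject_id}")
        ax.legend()
        return ax

    def plot_confusion(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.counts.as_matrix()
        ax.imshow(m, cmap="Blues")
        for (i, j), v in np.ndenumerate(m):
            ax.text(j, i, str(v), ha="center", va="center")
        ax.set_xticks([0, 1], ["absence", "fatigue"])
        ax.set_yticks([0, 1], ["absence", "fatigue"])
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        ax.set_title(f"subject {self.subject_id}")
        return ax


class SubjectFatigueModel:
    """User-tuned fatigue classifier for a single subject's feature matrix.

    Parameters
    ----------
    features : FeatureMatrix
        Windows-by-features matrix with the binary fatigue label vector.
    spec : ClassifierSpec
        Forest configuration and master random seed.
    """

    def __init__(self, features: FeatureMatrix, spec: ClassifierSpec = ClassifierSpec()):
        self.features = features
        self.spec = spec

    @classmethod
    def from_recording(
        cls,
        recording,
        spec: ClassifierSpec = ClassifierSpec(),
        *,
        constants=None,
        reference_policy=None,
        filter_spec=None,
        windowing=None,
        feature_defs=None,
    ) -> "SubjectFatigueModel":
        """Build the model from a raw intensity recording by running the
        full preprocessing chain (mBLL -> band-pass -> windows -> features)."""
        from .constants import DEFAULT_CONSTANTS
        from .features import DEFAULT_FEATURES, build_feature_matrix
        from .hemodynamics import ReferenceIntervalPolicy, intensity_to_chromophores
        from .preprocess import FilterSpec, WindowingSpec, bandpass, segment_and_label

        series = intensity_to_chromophores(
            recording,
            reference_policy or ReferenceIntervalPolicy(),
            constants or DEFAULT_CONSTANTS,
        )
        filtered = bandpass(series, filter_spec or FilterSpec())
        windows = segment_and_label(filtered, windowing or WindowingSpec())
        matrix = build_feature_matrix(windows, feature_defs or DEFAULT_FEATURES)
        return cls(matrix, spec)

    def fit(self, n_folds: int = 10) -> SubjectFatigueResults:
        """Run the stratified k-fold procedure and pool fold predictions."""
        fm = self.features
        X, y = fm.values, fm.labels
        class_counts = np.bincount(y, minlength=2)
        if class_counts.min() == 0:
            raise FoldError("both classes must be present")
        if n_folds > class_counts.min():
            raise FoldError(
                f"{n_folds} folds infeasible: smallest class has only "
                f"{class_counts.min()} windows"
            )
        seeds = _seed_stream(self.spec.random_seed)
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=next(seeds))

        y_pred = np.empty_like(y)
        y_score = np.empty(y.size)
        selected: list[tuple[str, ...]] = []
        test_sizes: list[int] = []
        for train_idx, test_idx in skf.split(X, y):
            fold_train = FeatureMatrix(
                X[train_idx], fm.feature_names, y[train_idx], subject_id=fm.subject_id
            )
            names, support = rfe_select(fold_train, self.spec, seed=next(seeds))
            rf = RandomForest(
                self.spec.n_trees, self.spec.min_samples_split, next(seeds)
            ).fit(X[np.ix_(train_idx, support)], y[train_idx])
            frac = rf.vote_fractions(X[np.ix_(test_idx, support)])
            y_score[test_idx] = frac
            y_pred[test_idx] = (frac > 0.5).astype(int)
            selected.append(names)
            test_sizes.append(int(test_idx.size))

        counts = ConfusionCounts.from_predictions(y, y_pred)
        m = compute_metrics(counts)
        auc = 100.0 * float(roc_auc_score(y, y_score))
        return SubjectFatigueResults(
            subject_id=fm.subject_id,
            counts=counts,
            accuracy=m["accuracy"],
            precision=m["precision"],
            recall=m["recall"],
            f1=m["f1"],
            auc_roc=auc,
            selected_features=tuple(selected),
            fold_test_sizes=tuple(test_sizes),
            y_true=y.copy(),
            y_pred=y_pred,
            y_score=y_score,
            spec=self.spec,
            n_folds=n_folds,
        )


def evaluate_subject(
    matrix: FeatureMatrix, spec: ClassifierSpec = ClassifierSpec(), k: int = 10
) -> SubjectFatigueResults:
    """Functional wrapper: fit a :class:`SubjectFatigueModel` with k folds."""
    return SubjectFatigueModel(matrix, spec).fit(n_folds=k)


@dataclass
class CohortResults:
    """Per-subject metric table plus cross-subject aggregates."""

    entries: tuple[SubjectFatigueResults, ...]
    accuracy_threshold: float = 70.0

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("cannot aggregate an empty cohort")

    def table(self) -> pd.DataFrame:
        return pd.DataFrame([e.to_row() for e in self.entries]).set_index("subject")

    def _stats(self, rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return rows.mean(axis=0), rows.std(axis=0, ddof=0)

    def aggregate(self) -> pd.DataFrame:
        """Mean +- population SD per metric over all subjects and over the
        subset of subjects with accuracy strictly above the threshold."""
        rows = np.array([[e.metrics()[m] for m in METRIC_NAMES] for e in self.entries])
        mean, sd = self._stats(rows)
        out = {
            "mean": mean,
            "sd": sd,
        }
        mask = rows[:, 0] > self.accuracy_threshold
        if mask.any():
            smean, ssd = self._stats(rows[mask])
            out[f"mean_gt{self.accuracy_threshold:.0f}"] = smean
            out[f"sd_gt{self.accuracy_threshold:.0f}"] = ssd
        return pd.DataFrame(out, index=list(METRIC_NAMES)).T

    def summary(self) -> str:
        agg = self.aggregate()
        mean, sd = agg.loc["mean"], agg.loc["sd"]
        lines = ["Cognitive-fatigue classification -- cohort report", ""]
        header = f"{'Subject':<10}" + "".join(f"{m:>11}" for m in METRIC_NAMES)
        lines.append(header)
        for e in self.entries:
            met = e.metrics()
            lines.append(
                f"{e.subject_id:<10}" + "".join(f"{met[m]:>11.2f}" for m in METRIC_NAMES)
            )
        lines.append(
            f"{'Average':<10}"
            + "".join(f"{mean[m]:>6.2f}±{sd[m]:.2f}"[:11].rjust(11) for m in METRIC_NAMES)
        )
        key = f"mean_gt{self.accuracy_threshold:.0f}"
        if key in agg.index:
            sub_n = int(
                np.sum([e.accuracy > self.accuracy_threshold for e in self.entries])
            )
            lines.append(
                f"\nSubjects with accuracy > {self.accuracy_threshold:.0f}% "
                f"(n={sub_n}): accuracy {agg.loc[key, 'accuracy']:.2f} ± "
                f"{agg.loc[key.replace('mean', 'sd'), 'accuracy']:.2f} %"
            )
        return "\n".join(lines)


def aggregate_report(entries, accuracy_threshold: float = 70.0) -> CohortResults:
    """Aggregate per-subject results into a cohort report."""
    return CohortResults(tuple(entries), accuracy_threshold)


def aggregate_metric(values, subset_threshold: float | None = None) -> tuple[float, float]:
    """Mean and population SD of a metric vector, optionally restricted to
    values strictly above ``subset_threshold``."""
    v = np.asarray(values, dtype=float)
    if subset_threshold is not None:
        v = v[v > subset_threshold]
    if v.size == 0:
        raise ValueError("no values to aggregate")
    return float(v.mean()), float(v.std(ddof=0))


__all__ = [
    "ClassifierSpec",
    "ConfusionCounts",
    "FoldError",
    "compute_metrics",
    "rfe_select",
    "SubjectFatigueModel",
    "SubjectFatigueResults",
    "evaluate_subject",
    "CohortResults",
    "aggregate_report",
    "aggregate_metric",
]
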