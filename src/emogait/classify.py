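"""Classifier benchmarking: 10-fold cross-validation and recognition rate.

The four benchmarked configurations mirror classic WEKA setups via
scikit-learn surrogates:

==============  =======================  ==========================================
algorithm       WEKA configuration       surrogate
==============  =======================  ==========================================
svm_rbf         LibSVM -S 0 -K 2         SVC(C=1, rbf, gamma=1/n_features), with
                                         fold-internal standardisation (RBF is
                                         scale-sensitive)
decision_tree   J48 -C 0.25 -M 2         DecisionTreeClassifier(min_samples_leaf=2,
                                         ccp_alpha=0.01) — cost-complexity pruning
                                         approximating confidence-0.25 pruning
random_forest   RandomForest -I 10       RandomForestClassifier(n_estimators=10)
random_tree     RandomTree -M 1.0        ExtraTreeClassifier(min_samples_leaf=1,
                                         max_features="sqrt"), unpruned
==============  =======================  ==========================================

The surrogate mapping is an approximation (J48's error-based pruning is
not CART cost-complexity pruning); equivalence with WEKA outputs is not
claimed.  The recognition rate is

    Q = (number of correctly classified samples) / (total samples)

pooled over the test folds of a stratified, seeded k-fold split.  By
default PCA feature selection is fitted inside each training fold and
applied to its test fold (no leakage); ``paper_mode`` instead fits the
selection once on the full dataset, which is how a fixed per-dataset
feature count is most plausibly obtained.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier, ExtraTreeClassifier

from . import selection as _selection
from .errors import TaskError
from .io_model import TASKS, LabelledDataset, assemble_task
from .features import FEATURE_NAMES

logger = logging.getLogger(__name__)

ALGORITHMS = ("svm_rbf", "decision_tree", "random_forest", "random_tree")


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier configuration; params are frozen at construction."""

    algorithm: str
    seed: int = 0
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise TaskError(f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}")

    def build(self):
        """Instantiate the scikit-learn estimator for this spec."""
        p = dict(self.params)
        if self.algorithm == "svm_rbf":
            return Pipeline(
                [
                    ("scale", StandardScaler()),
                    (
                        "svc",
                        SVC(
                            C=p.get("C", 1.0),
                            kernel="rbf",
                            gamma=p.get("gamma", "auto"),  # auto = 1/n_features
                            random_state=self.seed,
                        ),
                    ),
                ]
            )
        if self.algorithm == "decision_tree":
            return DecisionTreeClassifier(
                min_samples_leaf=int(p.get("min_samples_leaf", 2)),
                ccp_alpha=p.get("ccp_alpha", 0.01),
                random_state=self.seed,
            )
        if self.algorithm == "random_forest":
            return RandomForestClassifier(
                n_estimators=int(p.get("n_estimators", 10)), random_state=self.seed
            )
        return ExtraTreeClassifier(
            min_samples_leaf=int(p.get("min_samples_leaf", 1)),
            max_features="sqrt",
            random_state=self.seed,
        )


@dataclass(frozen=True)
class SelectionConfig:
    """How PCA selection participates in cross-validation."""

    threshold: float = 0.95
    loading_cutoff: float = 0.71
    paper_mode: bool = False  # True: fit PCA once on the full dataset
    enabled: bool = True


@dataclass(frozen=True)
class EvaluationResult:
    """Per-task/per-configuration recognition rate with fold accounting."""

    task: str
    site: str
    filter_w: int
    algorithm: str
    Q: float
    per_fold: tuple[tuple[int, int], ...]  # (n_correct, n_total) per fold
    confusion: pd.DataFrame  # class x class counts summed over folds
    n_retained: int | None
    seed: int

    def __post_init__(self) -> None:
        total_correct = sum(c for c, _ in self.per_fold)
        total = sum(n for _, n in self.per_fold)
        if total and abs(self.Q - total_correct / total) > 1e-12:
            raise TaskError("Q must equal pooled correct / total exactly")


def crossvalidate(
    dataset: LabelledDataset,
    spec: ClassifierSpec,
    k: int = 10,
    selection_cfg: SelectionConfig | None = None,
    filter_w: int = 0,
) -> EvaluationResult:
    """Stratified k-fold cross-validation of one classifier on one task.

    Within each fold the PCA selection (if enabled) is fitted on the
    training rows only, unless ``selection_cfg.paper_mode`` is set, in
    which case one selection is fitted on the full dataset up front.
    Deterministic given (dataset, spec, k, seed).
    """
    selection_cfg = selection_cfg or SelectionConfig()
    classes = sorted(set(dataset.y))
    if len(classes) < 2:
        raise TaskError(f"dataset for task {dataset.task!r} has a single class")
    min_count = min(np.sum(dataset.y == c) for c in classes)
    if min_count < k:
        logger.warning(
            "smallest class has %d members < %d folds; reducing folds", min_count, k
        )
        k = int(min_count)

    global_model = None
    n_retained: int | None = None
    if selection_cfg.enabled and selection_cfg.paper_mode:
        global_model = _selection.fit_select(dataset.X, selection_cfg.threshold)
        n_retained = global_model.n_retained

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=spec.seed)
    per_fold: list[tuple[int, int]] = []
    y_true_all: list[np.ndarray] = []
    y_pred_all: list[np.ndarray] = []
    retained_per_fold: list[int] = []
    for train_idx, test_idx in skf.split(dataset.X, dataset.y):
        X_train = dataset.X.iloc[train_idx]
        X_test = dataset.X.iloc[test_idx]
        y_train = dataset.y[train_idx]
        y_test = dataset.y[test_idx]
        if selection_cfg.enabled:
            model = global_model or _selection.fit_select(X_train, selection_cfg.threshold)
            retained_per_fold.append(model.n_retained)
            Xtr = _selection.transform(model, X_train)
            Xte = _selection.transform(model, X_test)
        else:
            Xtr = X_train.to_numpy(dtype=float)
            Xte = X_test.to_numpy(dtype=float)
        est = spec.build()
        est.fit(Xtr, y_train)
        y_pred = est.predict(Xte)
        per_fold.append((int(np.sum(y_pred == y_test)), len(y_test)))
        y_true_all.append(y_test)
        y_pred_all.append(y_pred)

    if n_retained is None and retained_per_fold:
        n_retained = int(np.median(retained_per_fold))
    y_true = np.concatenate(y_true_all)
    y_pred = np.concatenate(y_pred_all)
    conf = pd.DataFrame(
        confusion_matrix(y_true, y_pred, labels=classes), index=classes, columns=classes
    )
    q = float(sum(c for c, _ in per_fold)) / float(sum(n for _, n in per_fold))
    return EvaluationResult(
        task=dataset.task,
        site=dataset.site,
        filter_w=filter_w,
        algorithm=spec.algorithm,
        Q=q,
        per_fold=tuple(per_fold),
        confusion=conf,
        n_retained=n_retained,
        seed=spec.seed,
    )


def run_grid(
    feature_tables: Mapping[int, pd.DataFrame],
    tasks: Sequence[str] = tuple(TASKS),
    sites: Sequence[str] = ("wrist", "ankle"),
    algorithms: Sequence[str] = ALGORITHMS,
    k: int = 10,
    seed: int = 0,
    selection_cfg: SelectionConfig | None = None,
) -> pd.DataFrame:
    """Evaluate every (task, w, site, algorithm) cell of the experiment grid.

    ``feature_tables`` maps each moving-average width w to the per-segment
    feature table extracted under that filter.  Returns one row per cell
    with the recognition rate Q and the number of PCA-retained features;
    a cell whose data are missing is marked absent and the run continues.
    """
    rows = []
    results: list[EvaluationResult | None] = []
    for task in tasks:
        for w, table in feature_tables.items():
            for site in sites:
                try:
                    dataset = assemble_task(table, task, site, FEATURE_NAMES)
                except Exception as exc:  # missing class/site → absent cell
                    logger.warning("grid cell (%s, w=%s, %s) absent: %s", task, w, site, exc)
                    for algorithm in algorithms:
                        rows.append(
                            dict(task=task, filter_w=w, site=site, algorithm=algorithm,
                                 Q=np.nan, n_retained=np.nan, n_samples=0)
                        )
                        results.append(None)
                    continue
                for algorithm in algorithms:
                    res = crossvalidate(
                        dataset,
                        ClassifierSpec(algorithm, seed=seed),
                        k=k,
                        selection_cfg=selection_cfg,
                        filter_w=w,
                    )
                    rows.append(
                        dict(
                            task=task,
                            filter_w=w,
                            site=site,
                            algorithm=algorithm,
                            Q=res.Q,
                            n_retained=res.n_retained,
                            n_samples=len(dataset),
                        )
                    )
                    results.append(res)
    table = pd.DataFrame(rows)
    table.attrs["results"] = results
    return table


def format_grid(table: pd.DataFrame, task: str) -> str:
    """Render one task's grid cells as a w × site by algorithm text table."""
    sub = table[table["task"] == task]
    pivot = sub.pivot_table(
        index=["filter_w", "site"], columns="algorithm", values="Q", sort=False
    )
    return f"task: {task}\n{pivot.to_string(float_format=lambda v: f'{100 * v:.1f}%')}"
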