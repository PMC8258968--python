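"""Movement-type classification with a linear SVM under nested CV.

Features are the per-cycle tri-axial binned accelerations (magnitude
excluded).  The outer loop is a structured 10-fold split holding out
exactly one cycle per participant per movement type; the inner loop
re-applies the same structured scheme to the training portion to tune
the SVM cost.  Significance comes from a label-permutation null: the
fold structure is a property of the experimental design, so it is built
from the design labels and held fixed while the target labels shuffle.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .datatypes import ClassificationResult, CycleSet, FeatureTable

__all__ = [
    "build_features",
    "make_structured_folds",
    "nested_cv_svm",
    "cross_classify",
    "permutation_test",
    "permutation_test_cross",
    "DEFAULT_C_GRID",
    "DEFAULT_N_FOLDS",
]

DEFAULT_N_FOLDS = 10
#: cost grid, log-spaced; the linear kernel has no other hyperparameter
DEFAULT_C_GRID = tuple(10.0**k for k in range(-3, 4))
#: libsvm iteration cap: large-C fits on unlearnable (permuted) labels
#: otherwise take minutes each; separable fits converge far below this
SVM_MAX_ITER = 10_000


def build_features(cycles: CycleSet) -> FeatureTable:
    """Concatenate the three axis bin-vectors of each cycle (Am excluded).

    Feature order is deterministic: ax bins 1..n, then ay, then az.
    """
    axes = ("ax", "ay", "az")
    X = np.concatenate([cycles.channel(c) for c in axes], axis=1)
    names = [f"{c}_bin{b + 1}" for c in axes for b in range(cycles.n_bins)]
    return FeatureTable(
        X=X,
        y=cycles.labels["movement_type"].to_numpy(),
        groups=cycles.labels["participant_id"].to_numpy(),
        source=str(cycles.labels["source"].iloc[0]) if len(cycles.labels) else "kid",
        feature_names=names,
    )


def make_structured_folds(
    table: FeatureTable,
    n_folds: int = DEFAULT_N_FOLDS,
    seed: int | None = 0,
    stratify_y: np.ndarray | None = None,
) -> np.ndarray:
    """Assign each cycle to a fold, stratified by participant x type.

    Every (participant, movement type) stratum must contain a multiple of
    ``n_folds`` cycles; with 10 cycles and 10 folds each fold receives
    exactly one cycle per stratum, i.e. ``participants x types`` cycles
    per fold.  Assignment is shuffled within each stratum by ``seed``.
    ``stratify_y`` overrides the labels used to define strata (needed when
    the target labels have been permuted but the design has not).
    """
    y = table.y if stratify_y is None else np.asarray(stratify_y)
    rng = np.random.default_rng(seed)
    folds = np.full(len(table), -1, dtype=np.intp)
    for pid in np.unique(table.groups):
        for cls in np.unique(y):
            idx = np.flatnonzero((table.groups == pid) & (y == cls))
            if idx.size == 0 or idx.size % n_folds:
                raise ValueError(
                    f"stratum (participant={pid!r}, type={cls!r}) has {idx.size} cycles, "
                    f"not divisible into {n_folds} folds"
                )
            rng.shuffle(idx)
            folds[idx] = np.tile(np.arange(n_folds), idx.size // n_folds)
    return folds


def _fit_svm(X: np.ndarray, y: np.ndarray, C: float) -> tuple[StandardScaler, SVC]:
    """Standardize on the given data only, then fit a one-vs-one linear SVM."""
    scaler = StandardScaler().fit(X)
    clf = SVC(kernel="linear", C=C, max_iter=SVM_MAX_ITER)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(scaler.transform(X), y)
    return scaler, clf


def _tune_C(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    stratify_y: np.ndarray,
    C_grid,
    seed: int | None,
    n_inner: int,
) -> float:
    """Pick the cost maximizing mean structured inner-CV accuracy.

    Ties go to the smallest cost, for determinism and maximal margin.
    """
    inner_table = FeatureTable(X=X, y=y, groups=groups, source="tuning")
    inner_folds = make_structured_folds(inner_table, n_inner, seed, stratify_y=stratify_y)
    scores = np.zeros(len(C_grid))
    for f in range(n_inner):
        tr, va = inner_folds != f, inner_folds == f
        for ci, C in enumerate(C_grid):
            scaler, clf = _fit_svm(X[tr], y[tr], C)
            scores[ci] += float(np.mean(clf.predict(scaler.transform(X[va])) == y[va]))
    return float(C_grid[int(np.argmax(scores))])


def _confusion_percent(y_true: np.ndarray, y_pred: np.ndarray, classes: list[str]) -> np.ndarray:
    counts = np.zeros((len(classes), len(classes)))
    index = {c: i for i, c in enumerate(classes)}
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return 100.0 * counts / totals


def _run_folded_svm(
    fit_table: FeatureTable,
    eval_table: FeatureTable,
    folds: np.ndarray,
    n_folds: int,
    C_grid,
    seed: int | None,
    tune: bool,
    fixed_C: float,
    stratify_y: np.ndarray,
) -> ClassificationResult:
    """Shared outer-fold loop for within- and cross-modality evaluation."""
    classes = sorted(np.unique(fit_table.y).tolist())
    accs, chosen = [], []
    y_true_all, y_pred_all = [], []
    for f in range(n_folds):
        tr, te = folds != f, folds == f
        if len(np.unique(fit_table.y[tr])) < 2:
            raise ValueError(f"training portion of fold {f} is degenerate (single class)")
        if tune:
            C = _tune_C(
                fit_table.X[tr],
                fit_table.y[tr],
                fit_table.groups[tr],
                stratify_y[tr],
                C_grid,
                seed,
                n_folds - 1,
            )
        else:
            C = fixed_C
        scaler, clf = _fit_svm(fit_table.X[tr], fit_table.y[tr], C)
        pred = clf.predict(scaler.transform(eval_table.X[te]))
        accs.append(float(np.mean(pred == eval_table.y[te])))
        chosen.append(C)
        y_true_all.append(eval_table.y[te])
        y_pred_all.append(pred)
    accs = np.asarray(accs)
    return ClassificationResult(
        fold_accuracies=accs,
        mean_accuracy=float(accs.mean()),
        sem=float(accs.std(ddof=1) / np.sqrt(n_folds)),
        confusion=_confusion_percent(
            np.concatenate(y_true_all), np.concatenate(y_pred_all), classes
        ),
        classes=classes,
        chosen_C=chosen,
    )


def nested_cv_svm(
    table: FeatureTable,
    n_folds: int = DEFAULT_N_FOLDS,
    C_grid=DEFAULT_C_GRID,
    seed: int | None = 0,
    tune: bool = True,
    fixed_C: float = 1.0,
    stratify_y: np.ndarray | None = None,
) -> ClassificationResult:
    """Structured nested cross-validation of the linear SVM.

    Per outer fold: tune the cost on inner structured folds drawn from the
    training portion only, standardize on the training portion only, refit
    on the full training portion and score the held-out fold.  With
    ``tune=False`` the cost is fixed at ``fixed_C`` (fast path for
    permutation nulls).
    """
    strat = table.y if stratify_y is None else np.asarray(stratify_y)
    folds = make_structured_folds(table, n_folds, seed, stratify_y=strat)
    return _run_folded_svm(
        table, table, folds, n_folds, C_grid, seed, tune, fixed_C, strat
    )


def cross_classify(
    train: FeatureTable,
    test: FeatureTable,
    n_folds: int = DEFAULT_N_FOLDS,
    C_grid=DEFAULT_C_GRID,
    seed: int | None = 0,
    tune: bool = True,
    fixed_C: float = 1.0,
    stratify_y: np.ndarray | None = None,
) -> ClassificationResult:
    """Train on one modality, evaluate on the other, fold by fold.

    The two tables must describe the same cycles (matched labels and
    groups row-for-row); the same structured outer folds are reused so
    fold accuracies are comparable with the within-modality run.  Tuning
    and fitting use the training modality exclusively.
    """
    if train.X.shape != test.X.shape:
        raise ValueError("feature tables have different shapes")
    if not (np.array_equal(train.y, test.y) and np.array_equal(train.groups, test.groups)):
        raise ValueError("cycle labels are not matched across modalities")
    strat = train.y if stratify_y is None else np.asarray(stratify_y)
    folds = make_structured_folds(train, n_folds, seed, stratify_y=strat)
    return _run_folded_svm(
        train, test, folds, n_folds, C_grid, seed, tune, fixed_C, strat
    )


def permutation_test(
    table: FeatureTable,
    observed_accuracy: float,
    n_perm: int = 100,
    seed: int | None = 0,
    n_folds: int = DEFAULT_N_FOLDS,
    C_grid=DEFAULT_C_GRID,
    retune: bool = True,
    scope: str = "global",
) -> tuple[np.ndarray, float]:
    """Label-permutation null distribution of the nested-CV accuracy.

    Movement-type labels are shuffled across all cycles
    (``scope='global'``) or within each participant
    (``scope='within_participant'``), the structured folds stay anchored
    to the design (original labels), and the full nested CV is recomputed
    per permutation.  ``retune=False`` skips inner tuning (fixed C), a
    documented fast path.  The p-value uses the add-one rule
    ``(1 + #{null >= observed}) / (1 + n_perm)``; its floor with 100
    permutations is 1/101.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if scope not in ("global", "within_participant"):
        raise ValueError("scope must be 'global' or 'within_participant'")
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        y_perm = table.y.copy()
        if scope == "global":
            rng.shuffle(y_perm)
        else:
            for pid in np.unique(table.groups):
                idx = np.flatnonzero(table.groups == pid)
                y_perm[idx] = y_perm[rng.permutation(idx)]
        perm_table = FeatureTable(
            X=table.X, y=y_perm, groups=table.groups, source=table.source
        )
        res = nested_cv_svm(
            perm_table,
            n_folds=n_folds,
            C_grid=C_grid,
            seed=int(rng.integers(2**31)),
            tune=retune,
            stratify_y=table.y,
        )
        null[i] = res.mean_accuracy
    p = (1.0 + float(np.sum(null >= observed_accuracy))) / (1.0 + n_perm)
    return null, p


def permutation_test_cross(
    train: FeatureTable,
    test: FeatureTable,
    observed_accuracy: float,
    n_perm: int = 100,
    seed: int | None = 0,
    n_folds: int = DEFAULT_N_FOLDS,
    C_grid=DEFAULT_C_GRID,
    retune: bool = True,
) -> tuple[np.ndarray, float]:
    """Permutation null for cross-modality classification.

    The shared cycle labels are shuffled once per permutation (the two
    tables stay matched) and the cross-classification is recomputed with
    design-anchored folds.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        y_perm = train.y.copy()
        rng.shuffle(y_perm)
        train_p = FeatureTable(X=train.X, y=y_perm, groups=train.groups, source=train.source)
        test_p = FeatureTable(X=test.X, y=y_perm, groups=test.groups, source=test.source)
        res = cross_classify(
            train_p,
            test_p,
            n_folds=n_folds,
            C_grid=C_grid,
            seed=int(rng.integers(2**31)),
            tune=retune,
            stratify_y=train.y,
        )
        null[i] = res.mean_accuracy
    p = (1.0 + float(np.sum(null >= observed_accuracy))) / (1.0 + n_perm)
    return null, p
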