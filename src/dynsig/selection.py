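"""Per-fold model selection for head-to-head comparison across families.

For families with more samples than features (one region, or one feature),
the candidate with the best in-sample training balanced accuracy is picked
per fold, and its test-fold accuracy is retained. For the large coupling
representations — where many candidates separate the training fold
perfectly — each candidate is first screened in a 10-PC space fit on the
training rows, and the winner's full-dimensional representation is then
scored on the test fold. Exact ties retain the mean of the tied candidates'
test accuracies. All selection decisions use training-fold information only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .cv import FoldPlan, _fit_fold, _impute_train_medians, balanced_accuracy, mixed_sigmoid_apply, mixed_sigmoid_fit
from .representations import RepresentationMatrix


@dataclass
class SelectionResult:
    family: str
    test_accuracies: np.ndarray  # one per fold (k*repeats)
    selected: list[tuple[str, ...]]  # tuple of tied model tags per fold
    plan: FoldPlan
    tie_folds: list[int] = field(default_factory=list)

    @property
    def mean_ba(self) -> float:
        return float(self.test_accuracies.mean())


def _fold_pipeline(X, y, train_idx, test_idx, C=1.0):
    """Impute + sigmoid-normalize + fit; returns (clf, X_tr, X_te)."""
    X_tr, X_te = _impute_train_medians(X[train_idx], X[test_idx])
    params = mixed_sigmoid_fit(X_tr)
    X_tr = mixed_sigmoid_apply(params, X_tr)
    X_te = mixed_sigmoid_apply(params, X_te)
    clf = _fit_fold(X_tr, y[train_idx], C)
    return clf, X_tr, X_te


def per_fold_best_selection(
    family: str,
    candidates: list[RepresentationMatrix],
    plan: FoldPlan,
    C: float = 1.0,
) -> SelectionResult:
    """Pick the best candidate per fold by in-sample training accuracy.

    All candidates must share labels (and hence the fold plan); the
    in-sample criterion refits the weighted classifier on the training rows
    and scores it on those same rows (no inner CV).
    """
    if not candidates:
        raise ValueError("no candidate representations supplied")
    y = candidates[0].y
    for c in candidates[1:]:
        if not np.array_equal(c.y, y):
            raise ValueError("candidates disagree on labels; fold plans would differ")
    test_bas, selected, tie_folds = [], [], []
    for fold_i, (train_idx, test_idx) in enumerate(plan.folds):
        train_scores, test_scores = [], []
        for rep in candidates:
            clf, X_tr, X_te = _fold_pipeline(rep.X, y, train_idx, test_idx, C)
            train_scores.append(balanced_accuracy(y[train_idx], clf.predict(X_tr)))
            test_scores.append(balanced_accuracy(y[test_idx], clf.predict(X_te)))
        train_scores = np.asarray(train_scores)
        best = np.flatnonzero(train_scores == train_scores.max())
        if best.size > 1:
            tie_folds.append(fold_i)
        test_bas.append(float(np.mean([test_scores[i] for i in best])))
        selected.append(tuple(candidates[i].tag for i in best))
    return SelectionResult(
        family=family,
        test_accuracies=np.array(test_bas),
        selected=selected,
        plan=plan,
        tie_folds=tie_folds,
    )


def pca_screen_spi_selection(
    family: str,
    candidates: list[RepresentationMatrix],
    plan: FoldPlan,
    n_pcs: int = 10,
    C: float = 1.0,
    fit_pca_per_fold: bool = True,
) -> SelectionResult:
    """Screen high-dimensional candidates in PC space, score winner in full space.

    Per fold: each candidate is reduced to its first ``n_pcs`` principal
    components (fit on the training rows by default; ``fit_pca_per_fold=False``
    reproduces a whole-data PCA variant) and the in-sample training balanced
    accuracy in PC space picks the winner, whose full representation is then
    fit on the training fold and scored out of sample.
    """
    if not candidates:
        raise ValueError("no candidate representations supplied")
    y = candidates[0].y
    whole_pcas = None
    if not fit_pca_per_fold:
        whole_pcas = []
        for rep in candidates:
            X, _ = _impute_train_medians(rep.X, rep.X)
            whole_pcas.append(PCA(n_components=min(n_pcs, *X.shape)).fit(X))
    test_bas, selected, tie_folds = [], [], []
    for fold_i, (train_idx, test_idx) in enumerate(plan.folds):
        train_scores = []
        for ci, rep in enumerate(candidates):
            X_tr, X_te = _impute_train_medians(rep.X[train_idx], rep.X[test_idx])
            params = mixed_sigmoid_fit(X_tr)
            X_tr = mixed_sigmoid_apply(params, X_tr)
            if fit_pca_per_fold:
                n_comp = min(n_pcs, X_tr.shape[0] - 1, X_tr.shape[1])
                pca = PCA(n_components=n_comp).fit(X_tr)
            else:
                pca = whole_pcas[ci]
            Z_tr = pca.transform(X_tr)
            clf = _fit_fold(Z_tr, y[train_idx], C)
            train_scores.append(balanced_accuracy(y[train_idx], clf.predict(Z_tr)))
        train_scores = np.asarray(train_scores)
        best = np.flatnonzero(train_scores == train_scores.max())
        if best.size > 1:
            tie_folds.append(fold_i)
        fold_tests = []
        for i in best:
            clf, _, X_te = _fold_pipeline(candidates[i].X, y, train_idx, test_idx, C)
            fold_tests.append(balanced_accuracy(y[test_idx], clf.predict(X_te)))
        test_bas.append(float(np.mean(fold_tests)))
        selected.append(tuple(candidates[i].tag for i in best))
    return SelectionResult(
        family=family,
        test_accuracies=np.array(test_bas),
        selected=selected,
        plan=plan,
        tie_folds=tie_folds,
    )


def pca_reduce(
    rep: RepresentationMatrix,
    plan: FoldPlan,
    n_components: int = 25,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-fold PCA scores: components fit on training rows only.

    Returns one (train_scores, test_scores) pair per fold, components
    ordered by decreasing explained variance.
    """
    out = []
    for train_idx, test_idx in plan.folds:
        X_tr, X_te = _impute_train_medians(rep.X[train_idx], rep.X[test_idx])
        n_comp = min(n_components, X_tr.shape[0], X_tr.shape[1])
        pca = PCA(n_components=n_comp).fit(X_tr)
        out.append((pca.transform(X_tr), pca.transform(X_te)))
    return out
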