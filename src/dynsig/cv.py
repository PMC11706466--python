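"""Repeated stratified k-fold evaluation of class-weighted linear SVMs.

Fold-wise protocol: impute missing values with training-fold column medians,
normalize each column with an outlier-robust scaled sigmoid fit on the
training rows only, fit a linear (hinge-loss) SVM with C fixed and
inverse-probability sample weights, and score balanced accuracy and AUC on
the held-out rows. Two models evaluated under the same (labels, k, repeats,
seed) receive identical fold plans, which is what makes per-fold model
comparison and the corrected resampled t-test meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.svm import SVC

from .representations import RepresentationMatrix


# ------------------------------------------------------------ fold plans

@dataclass(frozen=True)
class FoldPlan:
    k: int
    repeats: int
    seed: int
    folds: tuple[tuple[np.ndarray, np.ndarray], ...]  # (train_idx, test_idx)

    @property
    def n_folds(self) -> int:
        return self.k * self.repeats


def make_fold_plan(y: np.ndarray, k: int = 10, repeats: int = 10, seed: int = 0) -> FoldPlan:
    """Stratified repeated k-fold plan, reproducible from (seed, labels)."""
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"cannot stratify {k} folds: smallest class has {counts.min()} samples"
        )
    splitter = RepeatedStratifiedKFold(n_splits=k, n_repeats=repeats, random_state=seed)
    folds = tuple(
        (np.array(tr), np.array(te)) for tr, te in splitter.split(np.zeros_like(y), y)
    )
    return FoldPlan(k=k, repeats=repeats, seed=seed, folds=folds)


# --------------------------------------------------- sigmoid normalization

@dataclass
class MixedSigmoidParams:
    """Per-column parameters of the scaled outlier-robust sigmoid."""

    center: np.ndarray
    scale: np.ndarray  # IQR/1.35 or SD fallback; 0 flags a constant column
    post_min: np.ndarray
    post_range: np.ndarray
    constant: np.ndarray  # boolean flags


def mixed_sigmoid_fit(train: np.ndarray) -> MixedSigmoidParams:
    """Fit the scaled robust sigmoid column-wise on training values.

    Columns with positive IQR use median and IQR/1.35 (the IQR of a normal
    is about 1.35 sigma); zero-IQR columns fall back to mean and SD; columns
    that are fully constant are flagged and map everything to 0.5. After the
    sigmoid, each column is linearly rescaled so the training values span
    [0, 1]; the same affine map is applied unchanged to test values.
    """
    train = np.asarray(train, dtype=float)
    if train.shape[0] < 3:
        raise ValueError("mixed sigmoid needs >= 3 training values per column")
    q75, q50, q25 = np.nanpercentile(train, [75, 50, 25], axis=0)
    iqr = q75 - q25
    mean = np.nanmean(train, axis=0)
    sd = np.nanstd(train, axis=0, ddof=1)
    use_iqr = iqr > 0
    center = np.where(use_iqr, q50, mean)
    scale = np.where(use_iqr, iqr / 1.35, sd)
    constant = scale == 0
    scale_safe = np.where(constant, 1.0, scale)
    g = 1.0 / (1.0 + np.exp(-(train - center) / scale_safe))
    lo = np.nanmin(g, axis=0)
    hi = np.nanmax(g, axis=0)
    rng = hi - lo
    rng = np.where(rng > 0, rng, 1.0)
    return MixedSigmoidParams(
        center=center,
        scale=scale_safe,
        post_min=np.where(constant, 0.0, lo),
        post_range=np.where(constant, 1.0, rng),
        constant=constant,
    )


def mixed_sigmoid_apply(params: MixedSigmoidParams, values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    g = 1.0 / (1.0 + np.exp(-(values - params.center) / params.scale))
    out = (g - params.post_min) / params.post_range
    out = np.where(params.constant, 0.5, out)
    return out


# ------------------------------------------------------------- metrics

def balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """(sensitivity + specificity) / 2, as a percentage."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    classes = np.unique(y_true)
    if classes.size != 2:
        raise ValueError("balanced accuracy needs both classes present in y_true")
    rates = [np.mean(y_pred[y_true == c] == c) for c in classes]
    return float(100.0 * np.mean(rates))


# ------------------------------------------------------------- evaluation

@dataclass
class CVEvaluation:
    """Out-of-sample per-fold metrics for one model."""

    model_tag: str
    balanced_accuracies: np.ndarray  # k*repeats values, percent
    aucs: np.ndarray
    plan: FoldPlan
    train_accuracies: np.ndarray | None = None
    settings: dict = field(default_factory=dict)

    @property
    def mean_ba(self) -> float:
        return float(self.balanced_accuracies.mean())

    @property
    def sd_ba(self) -> float:
        return float(self.balanced_accuracies.std(ddof=1))

    def summary(self) -> str:
        return f"{self.model_tag}: {self.mean_ba:.1f} ± {self.sd_ba:.1f}%"


def _impute_train_medians(train: np.ndarray, test: np.ndarray):
    med = np.nanmedian(train, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    tr = np.where(np.isnan(train), med, train)
    te = np.where(np.isnan(test), med, test)
    return tr, te


def _fit_fold(X_tr, y_tr, C: float):
    n = y_tr.size
    weights = np.empty(n)
    for c in np.unique(y_tr):
        weights[y_tr == c] = n / (2.0 * np.sum(y_tr == c))
    clf = SVC(kernel="linear", C=C)
    clf.fit(X_tr, y_tr, sample_weight=weights)
    return clf


def evaluate_on_plan(
    X: np.ndarray,
    y: np.ndarray,
    plan: FoldPlan,
    C: float = 1.0,
    model_tag: str = "",
    record_train: bool = False,
) -> CVEvaluation:
    """Run the full fold-wise pipeline on a design matrix under a fold plan."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    bas, aucs, train_bas = [], [], []
    for train_idx, test_idx in plan.folds:
        X_tr, X_te = _impute_train_medians(X[train_idx], X[test_idx])
        params = mixed_sigmoid_fit(X_tr)
        X_tr = mixed_sigmoid_apply(params, X_tr)
        X_te = mixed_sigmoid_apply(params, X_te)
        clf = _fit_fold(X_tr, y[train_idx], C)
        pred = clf.predict(X_te)
        bas.append(balanced_accuracy(y[test_idx], pred))
        scores = clf.decision_function(X_te)
        if np.unique(y[test_idx]).size == 2:
            aucs.append(float(roc_auc_score(y[test_idx], scores)))
        else:
            aucs.append(np.nan)
        if record_train:
            train_bas.append(balanced_accuracy(y[train_idx], clf.predict(X_tr)))
    return CVEvaluation(
        model_tag=model_tag,
        balanced_accuracies=np.array(bas),
        aucs=np.array(aucs),
        plan=plan,
        train_accuracies=np.array(train_bas) if record_train else None,
        settings={"C": C, "k": plan.k, "repeats": plan.repeats, "seed": plan.seed},
    )


def run_repeated_cv(
    rep: RepresentationMatrix,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
    C: float = 1.0,
    plan: FoldPlan | None = None,
) -> CVEvaluation:
    """10-repeat stratified 10-fold evaluation of one representation."""
    if plan is None:
        plan = make_fold_plan(rep.y, k=k, repeats=repeats, seed=seed)
    return evaluate_on_plan(rep.X, rep.y, plan, C=C, model_tag=rep.tag)


def confound_cv(
    covariates: np.ndarray,
    labels: np.ndarray,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
    C: float = 1.0,
    representation: RepresentationMatrix | None = None,
) -> CVEvaluation:
    """Evaluate covariate columns (optionally next to a representation)
    under the identical pipeline — the baseline any imaging-derived model
    must beat."""
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != np.asarray(labels).size:
        cov = cov.T
    X = cov
    tag = "confounds"
    if representation is not None:
        X = np.hstack([representation.X, cov])
        tag = f"{representation.tag}+confounds"
    plan = make_fold_plan(np.asarray(labels), k=k, repeats=repeats, seed=seed)
    return evaluate_on_plan(X, np.asarray(labels), plan, C=C, model_tag=tag)
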