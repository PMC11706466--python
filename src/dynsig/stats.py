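"""Significance machinery: permutation nulls, FDR control, model comparison.

Chance-level calibration uses label-permutation nulls: the labels are
shuffled once per permutation, the full repeated-CV harness is re-run, and
the mean fold balanced accuracy is recorded. Because the nulls are close to
Gaussian, a two-moment normal approximation of the null CDF gives one-tailed
p-values far below the 1/n_perm resolution of the raw permutation test.
Model pairs evaluated on shared folds are compared with the corrected
resampled t-test, whose variance term is inflated to account for the overlap
of training sets across folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .cv import CVEvaluation, FoldPlan, evaluate_on_plan, make_fold_plan
from .representations import RepresentationMatrix


@dataclass
class NullDistribution:
    model_tag: str
    n_perm: int
    null_means: np.ndarray  # one mean balanced accuracy per permutation, %
    seed: int

    @property
    def mu(self) -> float:
        return float(self.null_means.mean())

    @property
    def sigma(self) -> float:
        return float(self.null_means.std(ddof=1))


def permutation_null(
    rep: RepresentationMatrix,
    n_perm: int = 1000,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
    C: float = 1.0,
    light: bool = False,
) -> NullDistribution:
    """Label-permutation null of the mean cross-validated balanced accuracy.

    Each permutation shuffles the labels once, then runs the full
    ``repeats`` x ``k``-fold harness with stratification on the shuffled
    labels (preserving class counts within folds). ``light=True`` runs a
    single repeat inside each permutation — an explicitly approximate mode
    for desk-scale exploration. The shuffle stream is independent of the
    fold-plan seed.
    """
    if n_perm < 50:
        raise ValueError("permutation null needs n_perm >= 50")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    inner_repeats = 1 if light else repeats
    means = np.empty(n_perm)
    for p in range(n_perm):
        y_perm = rng.permutation(rep.y)
        plan = make_fold_plan(y_perm, k=k, repeats=inner_repeats, seed=seed + p)
        ev = evaluate_on_plan(rep.X, y_perm, plan, C=C, model_tag=f"{rep.tag}[perm]")
        means[p] = ev.mean_ba
    null = NullDistribution(
        model_tag=rep.tag, n_perm=n_perm, null_means=means, seed=seed
    )
    if null.sigma == 0:
        raise ValueError("degenerate permutation null: zero spread")
    return null


def gaussian_tail_p(observed_mean_ba: float, null: NullDistribution) -> float:
    """One-tailed p under the two-moment Gaussian fit of the null."""
    z = (observed_mean_ba - null.mu) / null.sigma
    p = float(sps.norm.sf(z))
    return min(max(p, np.finfo(float).tiny), 1.0 - np.finfo(float).eps)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def corrected_resampled_ttest(
    fold_ba_a: np.ndarray,
    fold_ba_b: np.ndarray,
    k: int,
    repeats: int,
    n_train: int,
    n_test: int,
) -> tuple[float, float]:
    """Corrected resampled t-test for repeated k-fold CV model comparison.

    T = d_bar / sqrt((1/(k*r) + n_test/n_train) * s_d^2) with k*r - 1
    degrees of freedom; the n_test/n_train term inflates the variance to
    account for overlapping training sets across folds.
    """
    a = np.asarray(fold_ba_a, dtype=float)
    b = np.asarray(fold_ba_b, dtype=float)
    n = k * repeats
    if a.size != n or b.size != n:
        raise ValueError(f"expected {n} fold metrics per model, got {a.size}/{b.size}")
    d = a - b
    dbar = d.mean()
    s2 = d.var(ddof=1)
    if s2 == 0:
        if dbar == 0:
            return 0.0, 1.0
        raise ValueError("zero variance with nonzero mean difference: T undefined")
    T = dbar / np.sqrt((1.0 / n + n_test / n_train) * s2)
    p = float(2.0 * sps.t.sf(abs(T), df=n - 1))
    return float(T), p


def compare_models(
    ev_a: CVEvaluation, ev_b: CVEvaluation
) -> tuple[float, float]:
    """Corrected resampled t-test between two evaluations on shared folds."""
    plan_a, plan_b = ev_a.plan, ev_b.plan
    if (plan_a.k, plan_a.repeats, plan_a.seed) != (plan_b.k, plan_b.repeats, plan_b.seed):
        raise ValueError("evaluations were not run on a shared fold plan")
    n_test = int(np.mean([te.size for _, te in plan_a.folds]))
    n_train = int(np.mean([tr.size for tr, _ in plan_a.folds]))
    return corrected_resampled_ttest(
        ev_a.balanced_accuracies,
        ev_b.balanced_accuracies,
        plan_a.k,
        plan_a.repeats,
        n_train,
        n_test,
    )


def similarity_index(values_a, values_b, absolute: bool = True) -> float:
    """Spearman rank correlation between two pooled value vectors.

    With ``absolute=True`` this is the similarity score used to cluster
    features or coupling statistics by their empirical behavior; the signed
    variant compares classification profiles between cohorts.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("similarity index needs equal-length vectors, length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("similarity index undefined for constant vectors")
    rho = sps.spearmanr(a, b).statistic
    return float(abs(rho)) if absolute else float(rho)
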