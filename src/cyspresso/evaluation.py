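"""Experiment machinery: folds, cross-validation, metrics and model comparison.

The evaluation protocol mirrors how partitioned expressibility classifiers
are benchmarked:

* stratified "balanced" k-fold plans where each fold holds an equal share
  of expressing / non-expressing knottins and non-knottins, reusable across
  representation types (the same-shuffle contract);
* tenfold cross-validation reporting per-fold ROC AUC, mean and SD;
* leave-one-out cross-validation that aggregates each sample's held-out
  confidence into one ROC curve and a 0.5-threshold confusion matrix;
* model ranking over repeated stratified 90-10 splits with a
  Friedman + Nemenyi critical-difference grouping;
* a paired two-tailed permutation test on AUC, and the Mann-Whitney U test
  used for confidence-track comparisons.

AUC here is always the rank-based (Mann-Whitney) statistic with ties
credited 0.5, i.e. U / (n_pos * n_neg) exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

#: a model under evaluation: maps (train indices, test indices) -> test scores
TrainScoreFn = Callable[[np.ndarray, np.ndarray], np.ndarray]


# ---------------------------------------------------------------------------
# fold plans
# ---------------------------------------------------------------------------

STRATUM_NAMES = (
    "non_knottin/not_expressed",
    "non_knottin/expressed",
    "knottin/not_expressed",
    "knottin/expressed",
)


@dataclass(frozen=True)
class FoldPlan:
    """Assignment of each record to one of k folds, stratified 2x2."""

    k: int
    assignment: np.ndarray  # fold index per record
    strata: np.ndarray      # stratum cell per record (0..3)
    seed: int

    @property
    def n(self) -> int:
        return self.assignment.size

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)


def stratum_cells(is_knottin: np.ndarray, expressed: np.ndarray) -> np.ndarray:
    """Map (knottin, expressed) flags to the 4 stratum cells."""
    return (
        2 * np.asarray(is_knottin, dtype=int) + np.asarray(expressed, dtype=int)
    )


def make_balanced_folds(
    is_knottin: np.ndarray,
    expressed: np.ndarray,
    k: int = 10,
    seed: int = 0,
) -> FoldPlan:
    """Deal records into k folds, balanced within each of the 4 strata.

    Within each stratum the records are shuffled by ``seed`` and dealt
    round-robin, so per-stratum fold counts differ by at most one.  The
    plan depends only on (flags, k, seed) and can therefore be reused
    across representation types.  A stratum smaller than k leaves some
    folds without that stratum (warning, not an error).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    strata = stratum_cells(is_knottin, expressed)
    n = strata.size
    assignment = np.full(n, -1, dtype=np.int64)
    rng = np.random.default_rng(seed)
    for cell in range(4):
        members = np.flatnonzero(strata == cell)
        if members.size == 0:
            warnings.warn(f"stratum {STRATUM_NAMES[cell]!r} is empty; skipped", stacklevel=2)
            continue
        if members.size < k:
            warnings.warn(
                f"stratum {STRATUM_NAMES[cell]!r} has {members.size} < k={k} records; "
                "some folds will lack it",
                stacklevel=2,
            )
        order = rng.permutation(members)
        assignment[order] = np.arange(order.size) % k
    return FoldPlan(k=k, assignment=assignment, strata=strata, seed=seed)


def singleton_folds(n: int) -> FoldPlan:
    """A leave-one-out plan: each record is its own fold."""
    return FoldPlan(
        k=n,
        assignment=np.arange(n, dtype=np.int64),
        strata=np.zeros(n, dtype=np.int64),
        seed=0,
    )


# ---------------------------------------------------------------------------
# confusion matrices and scalar metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_from_scores(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> ConfusionMatrix:
    """Threshold scores (>= threshold is positive) against binary labels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pred = scores >= threshold
    return ConfusionMatrix(
        tp=int(np.sum(pred & labels)),
        fp=int(np.sum(pred & ~labels)),
        tn=int(np.sum(~pred & ~labels)),
        fn=int(np.sum(~pred & labels)),
    )


def metrics_from_confusion(
    cm: ConfusionMatrix, ndigits: int | None = None
) -> dict[str, float | None]:
    """Sensitivity, specificity, precision, accuracy and F1 from counts.

    A metric whose denominator is zero is reported as ``None`` (absent).
    Pass ``ndigits=3`` for table-style reporting; full precision is the
    default.
    """
    if cm.n == 0:
        raise ValueError("confusion matrix is all-zero")

    def ratio(num: int, den: int) -> float | None:
        if den == 0:
            return None
        value = num / den
        return round(value, ndigits) if ndigits is not None else value

    return {
        "sensitivity": ratio(cm.tp, cm.tp + cm.fn),
        "specificity": ratio(cm.tn, cm.tn + cm.fp),
        "precision": ratio(cm.tp, cm.tp + cm.fp),
        "accuracy": ratio(cm.tp + cm.tn, cm.n),
        "f1": ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn),
    }


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based ROC AUC with ties credited 0.5: U / (n_pos * n_neg)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    """AUC plus confusion-derived metrics for one evaluation."""

    auc: float
    confusion: ConfusionMatrix
    metrics: dict[str, float | None]
    scheme: str
    threshold: float = 0.5
    seed: int | None = None

    def to_report(self) -> dict[str, object]:
        out: dict[str, object] = {"scheme": self.scheme, "auc": round(self.auc, 3)}
        for key, value in self.metrics.items():
            out[key] = None if value is None else round(value, 3)
        for name in ("tp", "fp", "tn", "fn"):
            out[name] = getattr(self.confusion, name)
        return out


def report_from_scores(
    scores: np.ndarray,
    labels: np.ndarray,
    scheme: str,
    threshold: float = 0.5,
    seed: int | None = None,
) -> EvalReport:
    cm = confusion_from_scores(scores, labels, threshold)
    return EvalReport(
        auc=roc_auc(scores, labels),
        confusion=cm,
        metrics=metrics_from_confusion(cm),
        scheme=scheme,
        threshold=threshold,
        seed=seed,
    )


@dataclass
class CVResult:
    """Per-fold AUCs plus the aggregated out-of-fold confidences."""

    fold_aucs: list[float | None]
    oof_scores: np.ndarray
    plan: FoldPlan

    @property
    def valid_aucs(self) -> np.ndarray:
        return np.array([a for a in self.fold_aucs if a is not None], dtype=float)

    @property
    def mean_auc(self) -> float:
        return float(self.valid_aucs.mean())

    @property
    def sd_auc(self) -> float:
        return float(self.valid_aucs.std(ddof=1)) if self.valid_aucs.size > 1 else 0.0


def cross_validate(
    train_and_score: TrainScoreFn, y: np.ndarray, plan: FoldPlan
) -> CVResult:
    """Run the fold plan: fit on k-1 folds, score the held-out fold.

    ``train_and_score(train_idx, test_idx)`` returns scores for
    ``test_idx``; models that need feature matrices close over them.  A
    fold whose training labels are single-class is skipped with a warning
    (its out-of-fold scores stay NaN); a fold whose *test* labels are
    single-class contributes scores but no per-fold AUC.
    """
    y = np.asarray(y).astype(int)
    oof = np.full(y.size, np.nan)
    fold_aucs: list[float | None] = []
    for fold in range(plan.k):
        test_idx = plan.fold_indices(fold)
        if test_idx.size == 0:
            fold_aucs.append(None)
            continue
        train_idx = np.flatnonzero(plan.assignment != fold)
        if np.unique(y[train_idx]).size < 2:
            warnings.warn(f"fold {fold}: single-class training set, skipped", stacklevel=2)
            fold_aucs.append(None)
            continue
        scores = np.asarray(train_and_score(train_idx, test_idx), dtype=float)
        oof[test_idx] = scores
        if np.unique(y[test_idx]).size < 2:
            fold_aucs.append(None)
        else:
            fold_aucs.append(roc_auc(scores, y[test_idx]))
    return CVResult(fold_aucs=fold_aucs, oof_scores=oof, plan=plan)


def loocv(train_and_score: TrainScoreFn, y: np.ndarray) -> EvalReport:
    """Leave-one-out: n fits, held-out confidences aggregated into one ROC.

    The confusion matrix uses the 0.5 decision threshold; metrics follow
    from it; the AUC is the single "general" AUC over all aggregated
    confidences.
    """
    y = np.asarray(y).astype(int)
    n = y.size
    if n < 10:
        warnings.warn(f"leave-one-out on only {n} samples", stacklevel=2)
    result = cross_validate(train_and_score, y, singleton_folds(n))
    return report_from_scores(result.oof_scores, y, scheme="loocv")


# ---------------------------------------------------------------------------
# model ranking with critical-difference grouping
# ---------------------------------------------------------------------------


@dataclass
class RankingResult:
    """Mean AUC ranks over repeated stratified splits, with CD grouping."""

    model_names: list[str]
    mean_ranks: np.ndarray           # (n_models,)
    aucs: np.ndarray                 # (n_permutations, n_models)
    ranks: np.ndarray                # (n_permutations, n_models), 1 = best
    same_group: np.ndarray           # (n_models, n_models) bool, symmetric
    critical_difference: float
    friedman_p: float | None
    alpha: float
    n_permutations: int
    train_fraction: float

    def to_table(self) -> list[dict[str, object]]:
        """Plotting-ready rows for a critical-difference diagram."""
        order = np.argsort(self.mean_ranks)
        return [
            {
                "model": self.model_names[i],
                "mean_rank": float(self.mean_ranks[i]),
                "mean_auc": float(self.aucs[:, i].mean()),
                "group_with": [
                    self.model_names[j]
                    for j in range(len(self.model_names))
                    if j != i and self.same_group[i, j]
                ],
            }
            for i in order
        ]


def stratified_split(
    strata: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One stratified train/test split (per-stratum shuffling)."""
    train_parts, test_parts = [], []
    for cell in np.unique(strata):
        members = rng.permutation(np.flatnonzero(strata == cell))
        n_train = int(round(train_fraction * members.size))
        n_train = min(max(n_train, 1), members.size - 1) if members.size > 1 else 0
        train_parts.append(members[:n_train])
        test_parts.append(members[n_train:])
    return np.sort(np.concatenate(train_parts)), np.sort(np.concatenate(test_parts))


def nemenyi_critical_difference(n_models: int, n_blocks: int, alpha: float = 0.05) -> float:
    """Nemenyi critical difference for mean ranks over n_blocks datasets."""
    q = stats.studentized_range.ppf(1.0 - alpha, n_models, np.inf) / math.sqrt(2.0)
    return float(q * math.sqrt(n_models * (n_models + 1) / (6.0 * n_blocks)))


def rank_models(
    models: Mapping[str, TrainScoreFn],
    y: np.ndarray,
    strata: np.ndarray,
    n_permutations: int = 50,
    train_fraction: float = 0.9,
    alpha: float = 0.05,
    seed: int = 0,
) -> RankingResult:
    """Rank models by AUC over repeated stratified train/test splits.

    Every permutation draws one stratified split shared by all models;
    each model is trained on the train part and its AUC measured on the
    test part.  Models are ranked per permutation (1 = best, ties get
    average rank) and mean ranks compared by a Friedman omnibus followed
    by the Nemenyi critical difference at ``alpha``.  With exactly two
    models the Friedman test is undefined and the Nemenyi CD alone decides
    the grouping.
    """
    names = list(models)
    if len(names) < 2:
        raise ValueError("need at least 2 models to rank")
    if n_permutations < 2:
        raise ValueError("need at least 2 permutations")
    y = np.asarray(y).astype(int)
    strata = np.asarray(strata)
    rng = np.random.default_rng(seed)

    aucs = np.empty((n_permutations, len(names)))
    for p in range(n_permutations):
        train_idx, test_idx = stratified_split(strata, train_fraction, rng)
        for m, name in enumerate(names):
            scores = np.asarray(models[name](train_idx, test_idx), dtype=float)
            aucs[p, m] = roc_auc(scores, y[test_idx])

    # rank 1 = best AUC; ties share the average rank
    ranks = np.vstack([stats.rankdata(-row) for row in aucs])
    mean_ranks = ranks.mean(axis=0)

    cd = nemenyi_critical_difference(len(names), n_permutations, alpha)
    if len(names) >= 3:
        friedman_p = float(stats.friedmanchisquare(*(aucs[:, m] for m in range(len(names)))).pvalue)
    else:
        friedman_p = None
    if friedman_p is not None and friedman_p >= alpha:
        same = np.ones((len(names), len(names)), dtype=bool)
    else:
        diff = np.abs(mean_ranks[:, None] - mean_ranks[None, :])
        same = diff < cd
        np.fill_diagonal(same, True)
    return RankingResult(
        model_names=names,
        mean_ranks=mean_ranks,
        aucs=aucs,
        ranks=ranks,
        same_group=same,
        critical_difference=cd,
        friedman_p=friedman_p,
        alpha=alpha,
        n_permutations=n_permutations,
        train_fraction=train_fraction,
    )


# ---------------------------------------------------------------------------
# paired permutation test on AUC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PermutationTestResult:
    observed: float
    p_value: float
    n_iterations: int
    unit: str


def paired_permutation_test_scores(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    y: np.ndarray,
    n_iterations: int = 10_000,
    seed: int = 0,
    unit: str = "sample",
    folds: np.ndarray | None = None,
) -> PermutationTestResult:
    """Two-tailed paired permutation test on AUC from matched score vectors.

    The observed statistic is auc(A) - auc(B) over the shared out-of-fold
    confidences.  Under the null the two models are exchangeable, so each
    iteration swaps the per-sample score pair with probability 1/2
    (``unit="sample"``) or swaps whole folds (``unit="fold"``, requires
    ``folds``) and recomputes the statistic.  The p-value uses +1
    smoothing: (b + 1) / (m + 1).
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    y = np.asarray(y).astype(int)
    if unit not in ("sample", "fold"):
        raise ValueError(f"unknown permutation unit {unit!r}")
    if unit == "fold" and folds is None:
        raise ValueError("unit='fold' requires fold assignments")
    rng = np.random.default_rng(seed)
    observed = roc_auc(scores_a, y) - roc_auc(scores_b, y)
    count = 0
    for _ in range(n_iterations):
        if unit == "sample":
            mask = rng.integers(0, 2, size=y.size).astype(bool)
        else:
            fold_ids = np.unique(folds)
            swap_folds = fold_ids[rng.integers(0, 2, size=fold_ids.size).astype(bool)]
            mask = np.isin(folds, swap_folds)
        sa = np.where(mask, scores_b, scores_a)
        sb = np.where(mask, scores_a, scores_b)
        stat = roc_auc(sa, y) - roc_auc(sb, y)
        if abs(stat) >= abs(observed) - 1e-12:
            count += 1
    return PermutationTestResult(
        observed=float(observed),
        p_value=(count + 1) / (n_iterations + 1),
        n_iterations=n_iterations,
        unit=unit,
    )


def paired_permutation_test_auc(
    model_a: TrainScoreFn,
    model_b: TrainScoreFn,
    y: np.ndarray,
    plan: FoldPlan,
    n_iterations: int = 10_000,
    seed: int = 0,
    unit: str = "sample",
) -> PermutationTestResult:
    """Shared-fold CV for two models, then the paired permutation test."""
    result_a = cross_validate(model_a, y, plan)
    result_b = cross_validate(model_b, y, plan)
    ok = ~(np.isnan(result_a.oof_scores) | np.isnan(result_b.oof_scores))
    return paired_permutation_test_scores(
        result_a.oof_scores[ok],
        result_b.oof_scores[ok],
        np.asarray(y)[ok],
        n_iterations=n_iterations,
        seed=seed,
        unit=unit,
        folds=plan.assignment[ok],
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p_value: float
    method: str


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    U is the rank-sum statistic of sample ``a`` with midrank ties.  For
    min(n) <= 8 the permutation distribution of U is enumerated exactly
    (all C(n, n_a) assignments of the pooled values); otherwise the
    normal approximation with tie correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a, n_b = a.size, b.size
    u_obs = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)
    if min(n_a, n_b) <= 8 and math.comb(n_a + n_b, n_a) <= 200_000:
        mu = n_a * n_b / 2.0
        dev = abs(u_obs - mu)
        count = 0
        total = 0
        rank_sum_base = n_a * (n_a + 1) / 2.0
        for subset in combinations(range(n_a + n_b), n_a):
            u = ranks[list(subset)].sum() - rank_sum_base
            if abs(u - mu) >= dev - 1e-12:
                count += 1
            total += 1
        return MannWhitneyResult(u=u_obs, p_value=count / total, method="exact")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return MannWhitneyResult(u=float(res.statistic), p_value=float(res.pvalue), method="asymptotic")
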