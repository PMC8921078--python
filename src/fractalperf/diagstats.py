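"""Diagnostic-accuracy and agreement statistics.

Covers the evaluation arithmetic used for threshold-based grade prediction:
sensitivity/specificity with exact (Clopper-Pearson) binomial confidence
intervals, quadratic-weighted kappa with a seeded bootstrap CI, ROC AUC by
the rank (Mann-Whitney) estimator with DeLong variance and paired DeLong
AUC comparison, Youden-J cutoff selection, Kruskal-Wallis and pairwise
Mann-Whitney tests with Bonferroni adjustment, and inter-/intrareader
agreement (Cohen's kappa, Bland-Altman).

Report convention: percentages are rounded half-up to integers for table
parity; full precision is retained on the underlying objects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import InputError, UndefinedStatisticError


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class ProportionEstimate:
    """A proportion with its exact two-sided 95% binomial CI."""

    numerator: int
    denominator: int
    point: float  # fraction in [0, 1]
    ci_low: float
    ci_high: float

    @property
    def percent(self) -> float:
        return 100.0 * self.point

    def rounded(self) -> tuple[int, int, int]:
        """(point %, CI low %, CI high %) rounded half-up to integers."""
        return (
            round_half_up(100.0 * self.point),
            round_half_up(100.0 * self.ci_low),
            round_half_up(100.0 * self.ci_high),
        )


@dataclass(frozen=True)
class ConfusionCounts:
    """Dichotomized lesion counts for one pooled comparison."""

    tp: int
    fp: int
    tn: int
    fn: int
    pool: str = ""

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise InputError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def exact_proportion(k: int, n: int, alpha: float = 0.05) -> ProportionEstimate:
    """Exact (Clopper-Pearson) two-sided binomial interval for k successes
    out of n."""
    if n <= 0:
        raise UndefinedStatisticError("proportion undefined for zero denominator")
    lo, hi = proportion_confint(k, n, alpha=alpha, method="beta")
    return ProportionEstimate(numerator=k, denominator=n, point=k / n,
                              ci_low=float(lo), ci_high=float(hi))


def sens_spec(
    counts: ConfusionCounts, alpha: float = 0.05
) -> tuple[Optional[ProportionEstimate], Optional[ProportionEstimate]]:
    """Sensitivity and specificity with exact 95% CIs.

    Sensitivity is the fraction of correctly predicted lesions in the
    higher-grade pool, TP / (TP + FN); specificity TN / (TN + FP). A zero
    denominator leaves the affected metric undefined (None), never 0.
    """
    sens = (exact_proportion(counts.tp, counts.tp + counts.fn, alpha)
            if counts.tp + counts.fn > 0 else None)
    spec = (exact_proportion(counts.tn, counts.tn + counts.fp, alpha)
            if counts.tn + counts.fp > 0 else None)
    return sens, spec


def pooled_counts(
    pred: Sequence[int], ref: Sequence[int], split: int, pool: str = ""
) -> ConfusionCounts:
    """Confusion counts for the pooled dichotomy ``ref >= split`` vs lower,
    with predictions pooled the same way."""
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    if pred.shape != ref.shape:
        raise InputError("prediction and reference vectors differ in length")
    pos = ref >= split
    called = pred >= split
    return ConfusionCounts(
        tp=int(np.sum(pos & called)),
        fn=int(np.sum(pos & ~called)),
        tn=int(np.sum(~pos & ~called)),
        fp=int(np.sum(~pos & called)),
        pool=pool or f"{split - 1} vs {split}+",
    )


# ---------------------------------------------------------------------------
# weighted kappa


def _kappa_from_vectors(a: np.ndarray, b: np.ndarray, cats: np.ndarray, power: float) -> float:
    k = len(cats)
    index = {c: i for i, c in enumerate(cats)}
    obs = np.zeros((k, k))
    for x, y in zip(a, b):
        obs[index[x], index[y]] += 1
    n = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    i = np.arange(k)
    if power == 0:
        w = (i[:, None] != i[None, :]).astype(float)
    else:
        w = (np.abs(i[:, None] - i[None, :]) ** power) / float((k - 1) ** power)
    denom = (w * expected).sum()
    if denom == 0:
        raise UndefinedStatisticError("kappa undefined: no chance disagreement")
    return float(1.0 - (w * obs).sum() / denom)


def weighted_kappa(
    pred: Sequence,
    ref: Sequence,
    weighting: str = "quadratic",
    n_boot: int = 2000,
    seed: int = 0,
    ci: bool = False,
) -> float | tuple[float, tuple[float, float]]:
    """Chance-corrected agreement for ordinal labels.

    ``kappa = 1 - sum(w O) / sum(w E)`` with quadratic weights
    ``w_ij = (i - j)^2 / (K - 1)^2`` (``linear`` and ``unweighted`` are also
    available) and expected counts from the marginal products. With
    ``ci=True`` a seeded nonparametric bootstrap percentile interval
    (default 2000 resamples) is attached.
    """
    a = np.asarray(pred)
    b = np.asarray(ref)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("label vectors must be 1D and of equal length")
    cats = np.union1d(a, b)
    if len(cats) < 2:
        raise UndefinedStatisticError("kappa undefined with a single category")
    power = {"quadratic": 2.0, "linear": 1.0, "unweighted": 0.0}.get(weighting)
    if power is None:
        raise InputError(f"unknown weighting {weighting!r}")
    kappa = _kappa_from_vectors(a, b, cats, power)
    if not ci:
        return kappa
    rng = np.random.default_rng(seed)
    n = len(a)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            boots.append(_kappa_from_vectors(a[idx], b[idx], cats, power))
        except UndefinedStatisticError:
            continue
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return kappa, (float(lo), float(hi))


def cohens_kappa(a: Sequence, b: Sequence) -> float:
    """Unweighted Cohen's kappa."""
    return weighted_kappa(a, b, weighting="unweighted")


# ---------------------------------------------------------------------------
# ROC / AUC (rank estimator with DeLong variance)


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_structural(scores: np.ndarray, labels: np.ndarray):
    """DeLong placement values: AUC plus per-observation V10 / V01."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise InputError("both classes must be present for ROC analysis")
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(v10.mean())
    return auc, v10, v01


def roc_auc(
    scores: Sequence[float], labels: Sequence[bool], alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """AUC by the rank (Mann-Whitney) estimator with midrank tie handling,
    plus a DeLong asymptotic CI clipped to [0, 1]."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    auc, v10, v01 = _delong_structural(scores, labels)
    m, n = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * math.sqrt(max(var, 0.0))
    return auc, (max(0.0, auc - half), min(1.0, auc + half))


def compare_auc(
    scores_a: Sequence[float], scores_b: Sequence[float], labels: Sequence[bool]
) -> tuple[float, float, float]:
    """Paired DeLong test for two AUCs on the same cases.

    Returns (auc_a, auc_b, two-sided p). Degenerate zero variance with
    equal AUCs yields p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    auc_a, v10_a, v01_a = _delong_structural(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_structural(scores_b, labels)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc_a - auc_b
    if var <= 0:
        return auc_a, auc_b, 1.0 if diff == 0 else 0.0
    z = diff / math.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return auc_a, auc_b, float(p)


def youden_cutoff(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    A case is called positive when its score is strictly above the cutoff;
    candidate cutoffs are the observed scores. Ties in J resolve to the
    lower cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise InputError("both classes must be present for cutoff selection")
    candidates = np.unique(scores)
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    best_cut = candidates[0]
    best_j = -np.inf
    for c in candidates:  # ascending: lower cutoff wins ties
        called = scores > c
        j = np.sum(called & labels) / n_pos + np.sum(~called & ~labels) / n_neg - 1.0
        if j > best_j + 1e-12:
            best_j = j
            best_cut = c
    return float(best_cut)


# ---------------------------------------------------------------------------
# group tests


@dataclass
class GroupTestResult:
    kruskal_p: float
    pairwise: dict[tuple, float]  # raw two-sided Mann-Whitney p per pair
    pairwise_adjusted: dict[tuple, float]  # Bonferroni-adjusted, capped at 1


def group_tests(groups: dict) -> GroupTestResult:
    """Kruskal-Wallis across groups plus pairwise Mann-Whitney U tests with
    Bonferroni adjustment (multiply by the number of pairs, cap at 1).

    All-identical values across every group return p = 1 by contract.
    """
    keys = list(groups)
    if len(keys) < 2:
        raise InputError("need at least two groups")
    arrays = [np.asarray(groups[k], dtype=float) for k in keys]
    if any(a.size == 0 for a in arrays):
        raise InputError("every group needs at least one value")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        kw_p = 1.0
    else:
        kw_p = float(stats.kruskal(*arrays).pvalue)
    pairwise = {}
    pairs = list(combinations(range(len(keys)), 2))
    for i, j in pairs:
        a, b = arrays[i], arrays[j]
        both = np.concatenate([a, b])
        if np.all(both == both[0]):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue)
        pairwise[(keys[i], keys[j])] = p
    m = len(pairs)
    adjusted = {k: min(1.0, m * p) for k, p in pairwise.items()}
    return GroupTestResult(kruskal_p=kw_p, pairwise=pairwise, pairwise_adjusted=adjusted)


# ---------------------------------------------------------------------------
# reader agreement


@dataclass
class AgreementResult:
    kappa: float  # Cohen's kappa on categorized values
    bias: float  # mean difference a - b
    loa_low: float  # bias - 1.96 sd(diff)
    loa_high: float  # bias + 1.96 sd(diff)


def reader_agreement(values_a: Sequence[float], values_b: Sequence[float],
                     categorize=None) -> AgreementResult:
    """Paired-reader agreement: Bland-Altman bias and 95% limits of
    agreement on the raw values, Cohen's kappa on categorized values
    (``categorize`` defaults to the identity, for already-categorical
    input)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("paired vectors must be 1D and of equal length")
    if len(a) < 2:
        raise InputError("need at least two paired readings")
    diff = a - b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    cat_a = [categorize(x) for x in a] if categorize else a.tolist()
    cat_b = [categorize(x) for x in b] if categorize else b.tolist()
    try:
        kappa = cohens_kappa(cat_a, cat_b)
    except UndefinedStatisticError:
        kappa = 1.0 if cat_a == cat_b else float("nan")
    return AgreementResult(kappa=kappa, bias=bias,
                           loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd)
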