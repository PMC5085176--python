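"""Metrics and leakage-safe target cross-validation.

The metric set is parameterized by four counts: N+ and N− are the numbers
of true sites and non-sites examined, N−+ the true sites missed (false
negatives) and N+− the non-sites called positive (false positives).  Then

    Sn  = 1 − N−+/N+
    Sp  = 1 − N+−/N−
    Acc = 1 − (N−+ + N+−)/(N+ + N−)
    MCC = [1 − (N−+/N+ + N+−/N−)]
          / sqrt[(1 + (N+− − N−+)/N+) · (1 + (N−+ − N+−)/N−)]

which is algebraically the standard Matthews correlation coefficient in
TP/TN/FP/FN form — the parameterization just makes the boundary behavior
obvious (no errors → Acc = MCC = 1, all errors → MCC = −1, half errors in
each class → Acc = 0.5, MCC = 0).

Target cross-validation is an ordinary stratified K-fold with one hard
guarantee: the Monte Carlo class expansion happens inside each training
split, after the fold boundaries are fixed, so test folds contain only
experiment-confirmed samples.  An explicit audit raises if a synthetic
window or a train/test overlap ever reaches a test fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from carbonsite.classifier import RFConfig, train, score_windows
from carbonsite.errors import LeakageError
from carbonsite.montecarlo import expand_positives
from carbonsite.windows import PeptideWindow, SampleSet


@dataclass(frozen=True)
class ConfusionCounts:
    """The four counts behind the metric set.

    ``n_pos``/``n_neg`` are N+/N− (class sizes); ``fn`` is N−+ (true sites
    predicted negative); ``fp`` is N+− (non-sites predicted positive).
    Fractional values are allowed so that counts averaged over folds can be
    passed back through the same formulas.
    """

    n_pos: float
    n_neg: float
    fn: float = 0.0
    fp: float = 0.0

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("class sizes must be non-negative")
        if not 0 <= self.fn <= self.n_pos:
            raise ValueError(
                f"false negatives ({self.fn}) must lie in [0, N+={self.n_pos}]"
            )
        if not 0 <= self.fp <= self.n_neg:
            raise ValueError(
                f"false positives ({self.fp}) must lie in [0, N−={self.n_neg}]"
            )

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.n_pos + other.n_pos,
                               self.n_neg + other.n_neg,
                               self.fn + other.fn, self.fp + other.fp)


@dataclass(frozen=True)
class MetricsReport:
    """Sn/Sp/Acc/MCC (plus optional AUC) for one evaluation.

    ``mcc`` is None exactly when its denominator vanishes (a predicted
    class is empty); the ``mcc_undefined`` flag makes that explicit rather
    than substituting a number.
    """

    sn: float
    sp: float
    acc: float
    mcc: float | None
    counts: ConfusionCounts
    auc: float | None = None

    @property
    def mcc_undefined(self) -> bool:
        return self.mcc is None


def compute_metrics(counts: ConfusionCounts,
                    auc: float | None = None) -> MetricsReport:
    """Evaluate the four metrics from the counts."""
    n_pos, n_neg, fn, fp = counts.n_pos, counts.n_neg, counts.fn, counts.fp
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            "Sn and Sp require both N+ > 0 and N− > 0 "
            f"(got N+={n_pos}, N−={n_neg})"
        )
    sn = 1.0 - fn / n_pos
    sp = 1.0 - fp / n_neg
    acc = 1.0 - (fn + fp) / (n_pos + n_neg)
    denom_sq = (1.0 + (fp - fn) / n_pos) * (1.0 + (fn - fp) / n_neg)
    if denom_sq <= 0:
        mcc = None
    else:
        mcc = (1.0 - (fn / n_pos + fp / n_neg)) / math.sqrt(denom_sq)
    return MetricsReport(sn=sn, sp=sp, acc=acc, mcc=mcc, counts=counts,
                         auc=auc)


def roc_auc(scores: Sequence[float],
            labels: Sequence[bool]) -> tuple[list[tuple[float, float]], float]:
    """ROC points and the trapezoid AUC.

    Thresholds sweep every distinct score from high to low with ties
    grouped, giving points (FPR, TPR) from (0,0) to (1,1).  The trapezoid
    area equals the rank statistic P(score+ > score−) + ½·P(tie).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    points: list[tuple[float, float]] = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = len(s)
    while i < n:
        j = i
        while j < n and s[j] == s[i]:  # tie group enters together
            j += 1
        tp += int(y[i:j].sum())
        fp += (j - i) - int(y[i:j].sum())
        points.append((fp / n_neg, tp / n_pos))
        i = j
    auc = 0.0
    for (x0, y0), (x1, y1) in zip(points, points[1:]):
        auc += (x1 - x0) * (y0 + y1) / 2.0
    return points, auc


@dataclass(frozen=True)
class FoldSplit:
    """Stratified K-fold indices, positives and negatives split separately.

    ``pos_folds[k]`` / ``neg_folds[k]`` index into the sample set's
    positive / negative lists; within each subset the folds partition the
    indices and sizes differ by at most one.
    """

    k: int
    pos_folds: tuple[tuple[int, ...], ...]
    neg_folds: tuple[tuple[int, ...], ...]
    seed: int


def make_folds(sample_set: SampleSet, k: int = 10, seed: int = 0) -> FoldSplit:
    """Randomly partition each subset into K near-equal folds.

    Must run before any Monte Carlo expansion: synthetic samples present at
    split time are a hard error, because they could otherwise leak into a
    test fold.
    """
    if sample_set.has_synthetic():
        raise LeakageError(
            "fold splitting must happen before positive-class expansion; "
            "synthetic samples found in the sample set"
        )
    if k < 2:
        raise ValueError(f"K must be >= 2, got {k}")
    for name, size in (("positive", sample_set.n_positive),
                       ("negative", sample_set.n_negative)):
        if size < k:
            raise ValueError(
                f"{name} subset has {size} samples, fewer than K={k}"
            )
    rng = np.random.default_rng(seed)

    def split(n: int) -> tuple[tuple[int, ...], ...]:
        perm = rng.permutation(n)
        return tuple(tuple(int(i) for i in part)
                     for part in np.array_split(perm, k))

    return FoldSplit(k=k, pos_folds=split(sample_set.n_positive),
                     neg_folds=split(sample_set.n_negative), seed=seed)


@dataclass
class CVResult:
    """Everything the target cross-validation measured.

    Two aggregates are reported: ``aggregate`` applies the metric formulas
    once to the fold-averaged counts, and ``pooled`` applies them to the
    summed counts.  (With near-equal folds the two nearly coincide; both
    are kept because either reading of "average then score" is defensible.)
    ``auc`` is computed from the pooled scores of all held-out samples.
    """

    k: int
    seed: int
    fold_counts: list[ConfusionCounts]
    fold_metrics: list[MetricsReport]
    aggregate: MetricsReport
    pooled: MetricsReport
    auc: float
    roc_points: list[tuple[float, float]]
    scores: list[float] = field(default_factory=list)
    labels: list[bool] = field(default_factory=list)

    @property
    def mean_fold_metrics(self) -> dict[str, float | None]:
        """Per-fold metrics averaged — the alternative aggregation."""
        defined = [m.mcc for m in self.fold_metrics if m.mcc is not None]
        return {
            "sn": float(np.mean([m.sn for m in self.fold_metrics])),
            "sp": float(np.mean([m.sp for m in self.fold_metrics])),
            "acc": float(np.mean([m.acc for m in self.fold_metrics])),
            "mcc": float(np.mean(defined)) if defined else None,
        }

    def to_dict(self) -> dict:
        def metrics_dict(m: MetricsReport) -> dict:
            return {
                "sn": m.sn, "sp": m.sp, "acc": m.acc, "mcc": m.mcc,
                "counts": {"n_pos": m.counts.n_pos, "n_neg": m.counts.n_neg,
                           "fn": m.counts.fn, "fp": m.counts.fp},
            }

        return {
            "k": self.k,
            "seed": self.seed,
            "auc": self.auc,
            "fold_metrics": [metrics_dict(m) for m in self.fold_metrics],
            "aggregate_from_mean_counts": metrics_dict(self.aggregate),
            "aggregate_from_pooled_counts": metrics_dict(self.pooled),
            "mean_fold_metrics": self.mean_fold_metrics,
        }


def _audit_fold(train_windows: Sequence[PeptideWindow],
                test_windows: Sequence[PeptideWindow]) -> None:
    """Hard leakage audit for one round."""
    for w in test_windows:
        if w.synthetic:
            raise LeakageError(
                f"synthetic window {w.protein_id}:{w.center_position} "
                "found in a test fold"
            )
    train_keys = {w.key for w in train_windows if not w.synthetic}
    overlap = train_keys & {w.key for w in test_windows}
    if overlap:
        raise LeakageError(
            f"sites present in both train and test of the same round: "
            f"{sorted(overlap)[:5]}"
        )


def target_cross_validate(sample_set: SampleSet, k: int = 10, seed: int = 0,
                          rf_config: RFConfig | None = None,
                          alpha: float = 0.0,
                          fallback_policy: str = "marginal",
                          expand: bool = True) -> CVResult:
    """Leakage-safe K-fold cross-validation with in-fold class balancing.

    For each round: the held-out fold is set aside untouched; the training
    positives are expanded by Monte Carlo sampling to the size of the
    training negatives (profile fit from the original training positives
    only); the coupling model and forest are fit on the expanded training
    split; the held-out, experiment-confirmed samples are scored.  Counts
    are accumulated per fold, averaged over the K rounds and passed once
    through the metric formulas; the pooled-count aggregate and the
    pooled-score AUC are reported alongside.

    ``expand=False`` disables the balancing step (for studying its effect
    on sensitivity); everything else is unchanged.
    """
    if sample_set.has_synthetic():
        raise LeakageError(
            "target cross-validation requires an entirely "
            "experiment-confirmed sample set"
        )
    rf_config = rf_config or RFConfig()
    folds = make_folds(sample_set, k=k, seed=seed)

    fold_counts: list[ConfusionCounts] = []
    fold_metrics: list[MetricsReport] = []
    all_scores: list[float] = []
    all_labels: list[bool] = []

    for round_idx in range(k):
        test_pos = [sample_set.positives[i] for i in folds.pos_folds[round_idx]]
        test_neg = [sample_set.negatives[i] for i in folds.neg_folds[round_idx]]
        train_pos = [sample_set.positives[i]
                     for r in range(k) if r != round_idx
                     for i in folds.pos_folds[r]]
        train_neg = [sample_set.negatives[i]
                     for r in range(k) if r != round_idx
                     for i in folds.neg_folds[r]]

        if expand and len(train_pos) < len(train_neg):
            expansion = expand_positives(
                train_pos, target_count=len(train_neg),
                seed=seed * 10_000 + round_idx,
            )
            train_pos = train_pos + expansion.expanded

        _audit_fold(train_pos + train_neg, test_pos + test_neg)

        train_split = SampleSet(center_type=sample_set.center_type,
                                xi=sample_set.xi, positives=train_pos,
                                negatives=train_neg)
        predictor = train(train_split, config=rf_config, alpha=alpha,
                          fallback_policy=fallback_policy)

        threshold = rf_config.decision_threshold
        scored = score_windows(predictor, test_pos + test_neg)
        labels = [True] * len(test_pos) + [False] * len(test_neg)
        fn = sum(1 for (_, s), is_pos in zip(scored, labels)
                 if is_pos and s < threshold)
        fp = sum(1 for (_, s), is_pos in zip(scored, labels)
                 if not is_pos and s >= threshold)
        counts = ConfusionCounts(n_pos=len(test_pos), n_neg=len(test_neg),
                                 fn=fn, fp=fp)
        fold_counts.append(counts)
        fold_metrics.append(compute_metrics(counts))
        all_scores.extend(s for _, s in scored)
        all_labels.extend(labels)

    mean_counts = ConfusionCounts(
        n_pos=float(np.mean([c.n_pos for c in fold_counts])),
        n_neg=float(np.mean([c.n_neg for c in fold_counts])),
        fn=float(np.mean([c.fn for c in fold_counts])),
        fp=float(np.mean([c.fp for c in fold_counts])),
    )
    pooled_counts = ConfusionCounts(
        n_pos=sum(c.n_pos for c in fold_counts),
        n_neg=sum(c.n_neg for c in fold_counts),
        fn=sum(c.fn for c in fold_counts),
        fp=sum(c.fp for c in fold_counts),
    )
    roc_points, auc = roc_auc(all_scores, all_labels)
    aggregate = compute_metrics(mean_counts, auc=auc)
    pooled = compute_metrics(pooled_counts, auc=auc)

    # partition check: every original sample tested exactly once
    tested = sum(c.n_pos + c.n_neg for c in fold_counts)
    if tested != sample_set.n_positive + sample_set.n_negative:
        raise LeakageError(
            "test folds do not partition the sample set "
            f"({tested} tested vs {sample_set.n_positive + sample_set.n_negative})"
        )

    return CVResult(k=k, seed=seed, fold_counts=fold_counts,
                    fold_metrics=fold_metrics, aggregate=aggregate,
                    pooled=pooled, auc=auc, roc_points=roc_points,
                    scores=all_scores, labels=all_labels)
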