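"""Scoring against consensus ground truth.

Binary confusion matrices; accuracy/precision/recall/F1 with an explicit
undefined marker (``None``) for degenerate denominators; percentile
bootstrap confidence intervals; the label+disagreement stratified split;
agreed-case subsets; reviewer accuracies; and Pearson chi-square
comparisons. All formulas are implemented directly (the test suite checks
them against scipy/scikit-learn as independent oracles).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ContractError
from .labels import AccessLabel, BinaryLabel, consolidate_to_binary
from .corpus import ReviewRecord

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "precision", "recall", "f1")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ContractError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricSet:
    """Point metrics with optional bootstrap means and percentile CIs.

    A metric whose denominator is zero is ``None`` (the undefined marker).
    ``ci`` maps metric name to (lower, upper); ``bootstrap_mean`` to the
    mean over defined replicates; ``n_undefined_replicates`` counts skipped
    replicates per metric.
    """

    accuracy: float | None
    precision: float | None
    recall: float | None
    f1: float | None
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    bootstrap_mean: dict[str, float] = field(default_factory=dict)
    n_undefined_replicates: dict[str, int] = field(default_factory=dict)

    def rounded(self, digits: int = 3) -> dict[str, float | None]:
        return {
            name: (None if value is None else round(value, digits))
            for name, value in zip(METRIC_NAMES, (self.accuracy, self.precision, self.recall, self.f1))
        }

    def to_dict(self) -> dict:
        out: dict = dict(zip(METRIC_NAMES, (self.accuracy, self.precision, self.recall, self.f1)))
        if self.ci:
            out["ci"] = {k: list(v) for k, v in self.ci.items()}
        if self.bootstrap_mean:
            out["bootstrap_mean"] = dict(self.bootstrap_mean)
        if self.n_undefined_replicates:
            out["n_undefined_replicates"] = dict(self.n_undefined_replicates)
        return out


def _as_bool(labels: Sequence) -> np.ndarray:
    out = np.empty(len(labels), dtype=bool)
    for i, lab in enumerate(labels):
        if isinstance(lab, BinaryLabel):
            out[i] = lab is BinaryLabel.POSITIVE
        elif isinstance(lab, (bool, np.bool_, int, np.integer)):
            out[i] = bool(lab)
        elif isinstance(lab, str):
            out[i] = lab.strip().casefold() in {"positive", "1", "true", "yes"}
        else:
            raise ContractError(f"cannot interpret binary label {lab!r}")
    return out


def confusion(predictions: Sequence, truth: Sequence) -> ConfusionMatrix:
    """Binary confusion matrix; positive means access identified."""
    if len(predictions) != len(truth):
        raise ContractError("predictions and truth must have equal length")
    pred = _as_bool(predictions)
    true = _as_bool(truth)
    return ConfusionMatrix(
        tp=int(np.sum(pred & true)),
        fp=int(np.sum(pred & ~true)),
        fn=int(np.sum(~pred & true)),
        tn=int(np.sum(~pred & ~true)),
    )


def metrics(cm: ConfusionMatrix) -> MetricSet:
    """Accuracy, precision, recall and F1 from a confusion matrix.

    No rounding is applied here; round only at presentation time.
    """
    n = cm.n
    accuracy = (cm.tp + cm.tn) / n if n else None
    precision = cm.tp / (cm.tp + cm.fp) if (cm.tp + cm.fp) else None
    recall = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) else None
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricSet(accuracy=accuracy, precision=precision, recall=recall, f1=f1)


def harmonic_f1(precision: float, recall: float) -> float | None:
    """F1 as the harmonic mean of precision and recall."""
    if precision + recall == 0:
        return None
    return 2 * precision * recall / (precision + recall)


def _replicate_metrics(pred: np.ndarray, true: np.ndarray, idx: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorised metrics over bootstrap index matrix ``idx`` (iters, n).

    Undefined entries come back as NaN.
    """
    p = pred[idx]
    t = true[idx]
    tp = np.sum(p & t, axis=1).astype(float)
    fp = np.sum(p & ~t, axis=1).astype(float)
    fn = np.sum(~p & t, axis=1).astype(float)
    tn = np.sum(~p & ~t, axis=1).astype(float)
    n = idx.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        accuracy = (tp + tn) / n
        precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), np.nan)
        recall = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), np.nan)
        denom = precision + recall
        f1 = np.where(
            np.isnan(precision) | np.isnan(recall) | (denom == 0),
            np.nan,
            2 * precision * recall / np.where(denom == 0, 1, denom),
        )
    return {"accuracy": accuracy, "precision": precision, "recall": recall, "f1": f1}


def bootstrap_ci(
    predictions: Sequence,
    truth: Sequence,
    iterations: int = 5000,
    level: float = 0.95,
    seed: int | None = None,
) -> MetricSet:
    """Percentile-bootstrap CIs for all four metrics.

    Cases are resampled with replacement n-out-of-n per iteration.
    Replicates where a metric is undefined are skipped for that metric (and
    counted); if every replicate is undefined the metric's CI is omitted
    with a warning.
    """
    if len(predictions) < 2:
        raise ContractError("bootstrap requires at least 2 cases")
    if iterations < 1:
        raise ContractError("iterations must be >= 1")
    pred = _as_bool(predictions)
    true = _as_bool(truth)
    if pred.shape != true.shape:
        raise ContractError("predictions and truth must have equal length")
    point = metrics(confusion(predictions, truth))
    rng = np.random.default_rng(seed)
    n = len(pred)
    idx = rng.integers(0, n, size=(iterations, n))
    reps = _replicate_metrics(pred, true, idx)
    alpha = (1 - level) / 2
    ci: dict[str, tuple[float, float]] = {}
    boot_mean: dict[str, float] = {}
    undefined: dict[str, int] = {}
    for name, values in reps.items():
        finite = values[~np.isnan(values)]
        n_undef = int(np.isnan(values).sum())
        if n_undef:
            undefined[name] = n_undef
            logger.info("bootstrap: %d/%d replicates undefined for %s", n_undef, iterations, name)
        if finite.size == 0:
            warnings.warn(f"all bootstrap replicates undefined for {name}", stacklevel=2)
            continue
        lo, hi = np.percentile(finite, [100 * alpha, 100 * (1 - alpha)])
        ci[name] = (float(lo), float(hi))
        boot_mean[name] = float(finite.mean())
    return MetricSet(
        accuracy=point.accuracy,
        precision=point.precision,
        recall=point.recall,
        f1=point.f1,
        ci=ci,
        bootstrap_mean=boot_mean,
        n_undefined_replicates=undefined,
    )


@dataclass(frozen=True)
class SplitAssignment:
    """Per-case development/testing assignment."""

    assignment: dict[str, str]  # case id -> "development" | "testing"

    @property
    def development(self) -> list[str]:
        return [k for k, v in self.assignment.items() if v == "development"]

    @property
    def testing(self) -> list[str]:
        return [k for k, v in self.assignment.items() if v == "testing"]


def stratified_split(
    cases: Sequence[tuple[str, AccessLabel, bool]],
    fraction: float = 0.5,
    seed: int | None = None,
) -> SplitAssignment:
    """Split cases into development/testing, stratified by
    (four-category consensus, disagreement flag).

    Within each stratum cases are shuffled, then ``fraction`` of them go to
    development via largest-integer allocation; fractional remainders
    alternate between development and testing in stratum order, so split
    sizes within a stratum never differ by more than one case at
    fraction=0.5.
    """
    if not 0 < fraction < 1:
        raise ContractError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    strata: dict[tuple, list[str]] = {}
    for case_id, consensus, disagreement in cases:
        key = (AccessLabel.parse(consensus).value, bool(disagreement))
        strata.setdefault(key, []).append(case_id)
    assignment: dict[str, str] = {}
    extra_to_dev = True
    for key in sorted(strata):
        ids = list(strata[key])
        rng.shuffle(ids)
        exact = fraction * len(ids)
        n_dev = int(exact)
        if exact - n_dev > 1e-12:
            if extra_to_dev:
                n_dev += 1
            extra_to_dev = not extra_to_dev
        for cid in ids[:n_dev]:
            assignment[cid] = "development"
        for cid in ids[n_dev:]:
            assignment[cid] = "testing"
    return SplitAssignment(assignment=assignment)


def agreed_subset(reviews: Iterable[ReviewRecord]) -> list[str]:
    """Patient ids whose two initial reviewers agreed (no adjudication)."""
    return [r.patient_id for r in reviews if not r.had_disagreement]


def reviewer_accuracy(
    reviewer_labels: Mapping[str, Sequence[AccessLabel]],
    consensus: Sequence[AccessLabel],
) -> tuple[dict[str, float], float]:
    """Per-reviewer accuracy against consensus, plus the unweighted mean.

    Accuracy is computed on the binary consolidation, matching how the
    pipeline itself is scored. Reviewers with zero cases are excluded with
    a warning.
    """
    truth = [consolidate_to_binary(c) for c in consensus]
    per: dict[str, float] = {}
    for reviewer, labels in reviewer_labels.items():
        if len(labels) == 0:
            warnings.warn(f"reviewer {reviewer!r} has no cases; excluded", stacklevel=2)
            continue
        if len(labels) != len(truth):
            raise ContractError(f"labels for reviewer {reviewer!r} misaligned with consensus")
        binary = [consolidate_to_binary(lab) for lab in labels]
        per[reviewer] = sum(b is t for b, t in zip(binary, truth)) / len(truth)
    if not per:
        raise ContractError("no reviewer had any cases")
    return per, mean_accuracy(per.values())


def mean_accuracy(accuracies: Iterable[float]) -> float:
    """Unweighted mean of per-reviewer accuracies."""
    values = list(accuracies)
    if not values:
        raise ContractError("need at least one accuracy")
    return float(sum(values)) / len(values)


def _pearson_chi2(observed: np.ndarray) -> tuple[float, int, float]:
    observed = np.asarray(observed, dtype=float)
    row = observed.sum(axis=1, keepdims=True)
    col = observed.sum(axis=0, keepdims=True)
    total = observed.sum()
    expected = row @ col / total
    if np.any(expected == 0):
        warnings.warn("zero expected cell; chi-square undefined", stacklevel=3)
        return float("nan"), 0, float("nan")
    stat = float(np.sum((observed - expected) ** 2 / expected))
    df = (observed.shape[0] - 1) * (observed.shape[1] - 1)
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


def chi_square_compare(
    successes_a: int,
    n_a: int,
    successes_b: int,
    n_b: int,
    correction: bool = False,
) -> tuple[float, float]:
    """Pearson chi-square comparing two proportions (2x2, 1 df).

    ``correction`` applies the Yates continuity correction. Returns
    ``(statistic, p)``; a table with a zero margin yields NaNs with a
    warning.
    """
    if not (0 <= successes_a <= n_a and 0 <= successes_b <= n_b) or n_a <= 0 or n_b <= 0:
        raise ContractError("need 0 <= successes <= n and n > 0")
    observed = np.array(
        [[successes_a, n_a - successes_a], [successes_b, n_b - successes_b]],
        dtype=float,
    )
    row = observed.sum(axis=1, keepdims=True)
    col = observed.sum(axis=0, keepdims=True)
    total = observed.sum()
    if np.any(row == 0) or np.any(col == 0):
        warnings.warn("zero-margin 2x2 table; chi-square undefined", stacklevel=2)
        return float("nan"), float("nan")
    expected = row @ col / total
    diff = np.abs(observed - expected)
    if correction:
        diff = np.maximum(diff - 0.5, 0)
    stat = float(np.sum(diff**2 / expected))
    return stat, float(stats.chi2.sf(stat, 1))


def chi_square_distribution(
    counts_a: Mapping[str, int], counts_b: Mapping[str, int]
) -> tuple[float, int, float]:
    """Pearson chi-square on a k x 2 contingency table of category counts.

    Both mappings must cover the same categories; df = k - 1. Returns
    ``(statistic, df, p)``.
    """
    if set(counts_a) != set(counts_b):
        raise ContractError("category sets must match")
    if sum(counts_a.values()) <= 0 or sum(counts_b.values()) <= 0:
        raise ContractError("both samples need positive totals")
    cats = sorted(counts_a)
    observed = np.array(
        [[counts_a[c] for c in cats], [counts_b[c] for c in cats]], dtype=float
    ).T
    stat, df, p = _pearson_chi2(observed)
    return stat, df, p
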