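"""Discrimination metrics and statistical comparison.

AUROC (midrank Mann-Whitney), AUPRC (average precision), the DeLong test
for correlated ROC areas via structural components, and bootstrap-averaged
model evaluation with percentile confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "MetricCI",
    "BootstrapResult",
    "auroc",
    "auprc",
    "delong_test",
    "bootstrap_evaluate",
]


@dataclass(frozen=True)
class MetricCI:
    mean: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (self.lower <= self.mean <= self.upper):
            raise ValueError("CI must satisfy lower <= mean <= upper")


@dataclass
class BootstrapResult:
    """Per-replicate AUROC/AUPRC for each test set."""

    auroc: dict[str, list[float]] = field(default_factory=dict)
    auprc: dict[str, list[float]] = field(default_factory=dict)
    B: int = 0
    seed: int = 0


def _check_labels(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels).astype(int)
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return labels == 1, labels == 0


def auroc(scores, labels) -> float:
    """Midrank Mann-Whitney AUROC (ties receive half credit)."""
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_labels(labels)
    n1, n0 = int(pos.sum()), int(neg.sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def auprc(scores, labels) -> float:
    """Average precision: mean, over positives ranked by descending score,
    of precision at each positive's rank (ties broken by stable original
    index order)."""
    scores = np.asarray(scores, dtype=float)
    pos, _ = _check_labels(labels)
    if not pos.any():
        raise ValueError("at least one positive required")
    order = np.argsort(-scores, kind="stable")
    hits = pos[order].astype(float)
    cum_hits = np.cumsum(hits)
    ranks = np.arange(1, len(hits) + 1)
    precision_at_pos = (cum_hits / ranks)[hits == 1.0]
    return float(precision_at_pos.mean())


def _structural_components(scores: np.ndarray, pos: np.ndarray,
                           neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong V10 (per positive) and V01 (per negative) components."""
    sp = scores[pos][:, None]
    sn = scores[neg][None, :]
    psi = (sp > sn).astype(float) + 0.5 * (sp == sn)
    return psi.mean(axis=1), psi.mean(axis=0), float(psi.mean())


def delong_test(scores_a, scores_b, labels) -> tuple[float, float, float, float]:
    """DeLong comparison of two correlated AUROCs on paired scores.

    Returns (auc_a, auc_b, z, two-sided p).  A zero AUC difference with zero
    variance returns z = 0, p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("score vectors must be paired (same length)")
    pos, neg = _check_labels(labels)
    n1, n0 = int(pos.sum()), int(neg.sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    v10_a, v01_a, auc_a = _structural_components(scores_a, pos, neg)
    v10_b, v01_b, auc_b = _structural_components(scores_b, pos, neg)
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1) if n1 > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1) if n0 > 1 else np.zeros((2, 2))
    cov = s10 / n1 + s01 / n0
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 0:
        z = 0.0 if diff == 0 else np.sign(diff) * np.inf
    else:
        z = diff / np.sqrt(var_diff)
    p = 1.0 if z == 0.0 else float(2.0 * stats.norm.sf(abs(z)))
    return float(auc_a), float(auc_b), float(z), p


def _percentile_ci(values: list[float]) -> MetricCI:
    arr = np.asarray(values, dtype=float)
    lo, hi = np.percentile(arr, [2.5, 97.5])
    mean = float(arr.mean())
    return MetricCI(mean, min(float(lo), mean), max(float(hi), mean))


def _stratified_resample(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Resample with replacement within each outcome class, preserving the
    case count (avoids all-negative replicates at 0.2% prevalence)."""
    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)
    take = np.concatenate([
        rng.choice(idx_pos, size=len(idx_pos), replace=True),
        rng.choice(idx_neg, size=len(idx_neg), replace=True),
    ])
    return np.sort(take)


def bootstrap_evaluate(
    trainer,
    train_set: tuple[np.ndarray, np.ndarray],
    test_sets: dict[str, tuple[np.ndarray, np.ndarray]],
    B: int = 100,
    seed: int = 0,
    stratified: bool = True,
    meta: np.ndarray | None = None,
) -> tuple[BootstrapResult, dict[str, dict[str, MetricCI]]]:
    """Bootstrap-averaged evaluation.

    ``trainer(X, y, replicate_seed)`` must return a scoring callable
    ``score(X_test) -> probabilities``.  Each of the B replicates resamples
    the training set with replacement (stratified by outcome unless
    ``stratified=False``), refits, and scores every fixed test set.

    ``meta`` is an optional per-row annotation array (e.g. site labels);
    when given, the resampled annotations are passed to the trainer as a
    fourth argument.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    X, y = train_set
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    result = BootstrapResult(B=B, seed=seed)
    for name in test_sets:
        result.auroc[name] = []
        result.auprc[name] = []
    rng = np.random.default_rng(seed)
    for b in range(B):
        if stratified:
            take = _stratified_resample(y, rng)
        else:
            take = np.sort(rng.integers(0, len(y), size=len(y)))
        try:
            rep_seed = int(rng.integers(2 ** 31))
            if meta is None:
                score = trainer(X[take], y[take], rep_seed)
            else:
                score = trainer(X[take], y[take], rep_seed, meta[take])
        except Exception as exc:
            raise RuntimeError(f"trainer failed on replicate {b}") from exc
        for name, (Xt, yt) in test_sets.items():
            s = np.asarray(score(np.asarray(Xt, dtype=float)), dtype=float)
            result.auroc[name].append(auroc(s, yt))
            result.auprc[name].append(auprc(s, yt))
    cis = {
        name: {
            "auroc": _percentile_ci(result.auroc[name]),
            "auprc": _percentile_ci(result.auprc[name]),
        }
        for name in test_sets
    }
    return result, cis
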