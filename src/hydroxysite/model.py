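"""Nearest-neighbour classifier, jackknife evaluation and the IFS loop.

The classifier assigns a query peptide the class of its nearest training
peptide under the cosine distance

    D(u, v) = 1 − (u · v) / (‖u‖ ‖v‖),

which lies in [0, 2] and is undefined for zero-norm vectors (an error).
Performance is measured by jackknife (leave-one-out) cross-validation:
every sample is predicted by the classifier trained on the remaining
n − 1, and the confusion counts are summarized as sensitivity (Sn),
specificity (Sp), accuracy (AC) and the Matthews correlation
coefficient (MCC).

Incremental feature selection (IFS) evaluates the jackknife over the
nested feature sets S_k = {first k features of a ranked list} for
k = 1..max_k and selects the k with peak accuracy (smallest k on ties).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from hydroxysite.encoding import FeatureDescriptor, FeatureMatrix
from hydroxysite.mrmr import RankedFeatureList

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    sn: float
    sp: float
    ac: float
    mcc: float


def nna_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine distance 1 − cos(u, v); symmetric, in [0, 2]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal dimension")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine distance is undefined for zero-norm vectors")
    return float(1.0 - np.dot(u, v) / (nu * nv))


def _normalize_rows(values: np.ndarray, what: str) -> np.ndarray:
    norms = np.linalg.norm(values, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValueError(
            f"zero-norm {what} vectors at indices {zero.tolist()}: "
            "cosine distance undefined"
        )
    return values / norms[:, None]


def nna_predict(
    query: np.ndarray, train_values: np.ndarray, train_labels: np.ndarray
) -> int:
    """Label of the nearest training sample; ties break to the lowest
    training-sample index."""
    query = np.asarray(query, dtype=float)
    train_values = np.asarray(train_values, dtype=float)
    if train_values.ndim != 2 or train_values.shape[0] == 0:
        raise ValueError("training set must be a non-empty 2-D matrix")
    if query.shape != (train_values.shape[1],):
        raise ValueError(
            f"query dimension {query.shape} does not match training "
            f"dimension {train_values.shape[1]}"
        )
    qn = _normalize_rows(query[None, :], "query")[0]
    tn = _normalize_rows(train_values, "training")
    dist = 1.0 - tn @ qn
    return int(np.asarray(train_labels)[int(np.argmin(dist))])


def _normalize_neutral(values: np.ndarray) -> np.ndarray:
    """Row-normalize, mapping zero-norm rows to zero rows.

    A zero row has cosine similarity 0 with everything (distance 1),
    i.e. it is treated as carrying no directional information.  Under
    restricted feature subsets (small k in IFS) zero-norm sample vectors
    are routine — e.g. a single PSSM feature whose score is 0 — so the
    evaluation loop needs a deterministic convention rather than an
    error; ``zero_norm="error"`` restores strictness.
    """
    norms = np.linalg.norm(values, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    return values / safe[:, None]


def jackknife(
    matrix: FeatureMatrix,
    feature_subset: Sequence[FeatureDescriptor] | np.ndarray | None = None,
    zero_norm: str = "neutral",
) -> tuple[ConfusionCounts, MetricSet]:
    """Leave-one-out evaluation of the NNA on a feature subset.

    ``feature_subset`` may be descriptors, column indices, or None for
    all features.  Each sample is predicted from the remaining n − 1.
    ``zero_norm`` chooses how zero-norm sample vectors are handled:
    ``"neutral"`` (distance 1 to everything, default) or ``"error"``.
    """
    if feature_subset is None:
        cols = np.arange(matrix.n_features)
    elif len(feature_subset) and isinstance(feature_subset[0], FeatureDescriptor):
        cols = np.array([matrix.locate(d) for d in feature_subset], dtype=int)
    else:
        cols = np.asarray(feature_subset, dtype=int)
    values = matrix.values[:, cols]
    labels = matrix.labels
    n = len(labels)
    if n < 2 or len(np.unique(labels)) < 2:
        raise ValueError("jackknife needs ≥2 samples with both classes present")
    if zero_norm == "error":
        normed = _normalize_rows(values, "sample")
    elif zero_norm == "neutral":
        normed = _normalize_neutral(values)
    else:
        raise ValueError("zero_norm must be 'neutral' or 'error'")
    dist = 1.0 - normed @ normed.T
    np.fill_diagonal(dist, np.inf)
    pred = labels[np.argmin(dist, axis=1)]
    counts = _confusion(labels, pred)
    return counts, compute_metrics(counts)


def _confusion(labels: np.ndarray, pred: np.ndarray) -> ConfusionCounts:
    tp = int(np.sum((labels == 1) & (pred == 1)))
    fp = int(np.sum((labels == 0) & (pred == 1)))
    tn = int(np.sum((labels == 0) & (pred == 0)))
    fn = int(np.sum((labels == 1) & (pred == 0)))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """Sn, Sp, AC and MCC from confusion counts.

    Degenerate margins are handled explicitly: a success rate with an
    empty class is reported as 0, and MCC with a zero denominator is
    defined as 0 (logged), the conventional guard.
    """
    if c.n == 0:
        raise ValueError("empty confusion matrix")
    sn = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else 0.0
    ac = (c.tp + c.tn) / c.n
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        logger.info("MCC denominator is zero; reporting MCC = 0")
        mcc = 0.0
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return MetricSet(sn=sn, sp=sp, ac=ac, mcc=mcc)


@dataclass
class IFSResult:
    """Per-k jackknife performance over nested feature prefixes."""

    per_k: list[tuple[int, ConfusionCounts, MetricSet]]
    optimal_k: int
    optimal_metrics: MetricSet
    optimize: str = "ac"

    def curve(self) -> np.ndarray:
        """(k, Sn, Sp, AC, MCC) rows as a float array."""
        return np.array(
            [[k, m.sn, m.sp, m.ac, m.mcc] for k, _, m in self.per_k]
        )

    def to_tsv(self, path: str | Path) -> None:
        lines = ["k\tSn\tSp\tAC\tMCC"]
        for k, _, m in self.per_k:
            lines.append(f"{k}\t{m.sn:.6f}\t{m.sp:.6f}\t{m.ac:.6f}\t{m.mcc:.6f}")
        Path(path).write_text("\n".join(lines) + "\n")


def run_ifs(
    matrix: FeatureMatrix,
    ranked: RankedFeatureList,
    max_k: int | None = None,
    optimize: str = "ac",
    zero_norm: str = "neutral",
) -> IFSResult:
    """Jackknife every prefix S_1 ⊂ S_2 ⊂ … ⊂ S_max_k of the ranked list.

    The optimum is the smallest k attaining the maximal accuracy
    (or MCC when ``optimize="mcc"``).  The pairwise dot products are
    accumulated incrementally, so the whole curve costs O(max_k · n²).
    Zero-norm handling follows :func:`jackknife`.
    """
    if optimize not in ("ac", "mcc"):
        raise ValueError("optimize must be 'ac' or 'mcc'")
    if zero_norm not in ("neutral", "error"):
        raise ValueError("zero_norm must be 'neutral' or 'error'")
    if max_k is None:
        max_k = len(ranked)
    if not 1 <= max_k <= len(ranked):
        raise ValueError(f"max_k must be in 1..{len(ranked)}")
    labels = matrix.labels
    n = len(labels)
    if n < 2 or len(np.unique(labels)) < 2:
        raise ValueError("IFS needs ≥2 samples with both classes present")
    gram = np.zeros((n, n))
    sq_norms = np.zeros(n)
    per_k: list[tuple[int, ConfusionCounts, MetricSet]] = []
    for step in range(max_k):
        col = matrix.values[:, ranked.indices[step]]
        gram += np.outer(col, col)
        sq_norms += col * col
        zero = np.flatnonzero(sq_norms == 0)
        if zero.size and zero_norm == "error":
            raise ValueError(
                f"zero-norm sample vectors at k={step + 1}: {zero.tolist()}"
            )
        # zero-norm rows have an all-zero gram row, so dividing by a safe
        # norm of 1 yields similarity 0 (distance 1), matching jackknife
        norms = np.sqrt(sq_norms)
        safe = np.where(norms == 0, 1.0, norms)
        dist = 1.0 - gram / np.outer(safe, safe)
        np.fill_diagonal(dist, np.inf)
        pred = labels[np.argmin(dist, axis=1)]
        counts = _confusion(labels, pred)
        per_k.append((step + 1, counts, compute_metrics(counts)))
    key = (lambda m: m.ac) if optimize == "ac" else (lambda m: m.mcc)
    best = max(key(m) for _, _, m in per_k)
    optimal_k = next(k for k, _, m in per_k if key(m) == best)
    optimal_metrics = next(m for k, _, m in per_k if k == optimal_k)
    return IFSResult(
        per_k=per_k,
        optimal_k=optimal_k,
        optimal_metrics=optimal_metrics,
        optimize=optimize,
    )
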