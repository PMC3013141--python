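"""Feature ranking by Max-Relevance (MaxRel) and mRMR.

Relevance and redundancy are plug-in mutual information (log base 2 by
default) computed on a 3-state discretization of each feature: values
below mean − k·σ, within, and above mean + k·σ, with k = 1 by default.
Constant features map to the middle state.

MaxRel ranks features by MI with the class label, descending.  mRMR is
the standard greedy scheme: the first feature is the MaxRel top; each
subsequent feature maximizes relevance minus mean redundancy with the
already-selected set (the "difference"/MID scheme, default) or relevance
divided by mean redundancy ("quotient"/MIQ).  All ties break toward the
canonical (lower) column index, so ranked lists are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from hydroxysite.encoding import FeatureDescriptor, FeatureMatrix

MAXREL = "maxrel"
MRMR = "mrmr"

_N_STATES = 3


@dataclass
class RankedFeatureList:
    """Features in rank order (best first) with their selection scores.

    For ``criterion="maxrel"`` the score is MI with the class label; for
    ``"mrmr"`` it is the greedy selection score at the step the feature
    was chosen (relevance for the first feature).
    """

    indices: np.ndarray  # column indices into the source matrix
    descriptors: list[FeatureDescriptor]
    scores: np.ndarray
    criterion: str

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(set(self.indices.tolist())) != len(self.indices):
            raise ValueError("ranked list contains duplicate features")
        if not (len(self.indices) == len(self.descriptors) == len(self.scores)):
            raise ValueError("indices, descriptors and scores must align")

    def __len__(self) -> int:
        return len(self.indices)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["rank\tfeature\tscore\tcriterion"]
        for r, (d, s) in enumerate(zip(self.descriptors, self.scores), start=1):
            lines.append(f"{r}\t{d}\t{s:.6f}\t{self.criterion}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, matrix: FeatureMatrix) -> "RankedFeatureList":
        lines = Path(path).read_text().splitlines()
        descriptors, scores, criterion = [], [], MAXREL
        for line in lines[1:]:
            if not line.strip():
                continue
            _, dstr, score_s, criterion = line.split("\t")
            descriptors.append(FeatureDescriptor.parse(dstr))
            scores.append(float(score_s))
        indices = np.array([matrix.locate(d) for d in descriptors], dtype=int)
        return cls(indices, descriptors, np.asarray(scores), criterion)


def discretize(values: np.ndarray, k_sigma: float = 1.0) -> np.ndarray:
    """Map each feature column to 3 states split at mean ± k_sigma·σ.

    Returns an integer matrix with states {0: low, 1: mid, 2: high}.
    Constant columns (σ = 0) map entirely to the middle state.  The
    mapping is invariant under per-feature translation.
    """
    if k_sigma <= 0:
        raise ValueError("k_sigma must be positive")
    values = np.atleast_2d(np.asarray(values, dtype=float))
    mean = values.mean(axis=0)
    std = values.std(axis=0)
    lo = mean - k_sigma * std
    hi = mean + k_sigma * std
    states = np.ones(values.shape, dtype=np.int8)
    nonconst = std > 0
    states[:, nonconst] = (
        (values[:, nonconst] > lo[nonconst]).astype(np.int8)
        + (values[:, nonconst] >= hi[nonconst]).astype(np.int8)
    )
    return states


def mutual_information(x: np.ndarray, y: np.ndarray, base: float = 2.0) -> float:
    """Plug-in mutual information between two discrete vectors.

    Non-negative, symmetric, and equal to the entropy of ``x`` when
    ``y = x``.  Units follow ``base`` (bits for 2, nats for e).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 2:
        raise ValueError("need at least two observations")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx, ny = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny)
    return _mi_from_joint(joint[None, :, :], base)[0]


def _mi_from_joint(joint: np.ndarray, base: float) -> np.ndarray:
    """MI for a stack of contingency tables, shape (m, nx, ny) → (m,)."""
    n = joint.sum(axis=(1, 2), keepdims=True).astype(float)
    p = joint / n
    px = p.sum(axis=2, keepdims=True)
    py = p.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = p * np.log(p / (px * py))
    mi = np.nansum(term, axis=(1, 2)) / np.log(base)
    return np.maximum(mi, 0.0)


def _mi_columns(states: np.ndarray, y: np.ndarray, base: float) -> np.ndarray:
    """MI of every column of a 3-state matrix with a 3-state vector ``y``."""
    n, d = states.shape
    codes = states.astype(np.int64) * _N_STATES + y[:, None]
    codes += np.arange(d, dtype=np.int64)[None, :] * (_N_STATES * _N_STATES)
    counts = np.bincount(codes.ravel(), minlength=d * _N_STATES * _N_STATES)
    joint = counts.reshape(d, _N_STATES, _N_STATES)
    return _mi_from_joint(joint, base)


def _prepare(matrix: FeatureMatrix, k_sigma: float) -> tuple[np.ndarray, np.ndarray]:
    states = discretize(matrix.values, k_sigma=k_sigma)
    # class label as a 3-state vector (states 0/1 used)
    y = matrix.labels.astype(np.int8)
    return states, y


def rank_maxrel(
    matrix: FeatureMatrix,
    top_n: int = 500,
    k_sigma: float = 1.0,
    base: float = 2.0,
) -> RankedFeatureList:
    """Rank features by MI with the class label, descending.

    Ties break toward the canonical feature order (lower column index).
    """
    top_n = min(top_n, matrix.n_features)
    states, y = _prepare(matrix, k_sigma)
    relevance = _mi_columns(states, y, base)
    # stable mergesort on -relevance keeps canonical order within ties
    order = np.argsort(-relevance, kind="stable")[:top_n]
    return RankedFeatureList(
        indices=order,
        descriptors=[matrix.descriptors[j] for j in order],
        scores=relevance[order],
        criterion=MAXREL,
    )


def rank_mrmr(
    matrix: FeatureMatrix,
    top_n: int = 500,
    scheme: str = "difference",
    k_sigma: float = 1.0,
    base: float = 2.0,
) -> RankedFeatureList:
    """Greedy mRMR ranking.

    The first feature is the MaxRel top.  At each later step the feature
    maximizing ``relevance − mean(redundancy)`` (difference scheme) or
    ``relevance / mean(redundancy)`` (quotient scheme; the denominator is
    floored at a small epsilon) over already-selected features is added.
    """
    if scheme not in ("difference", "quotient"):
        raise ValueError(f"unknown mRMR scheme {scheme!r}")
    top_n = min(top_n, matrix.n_features)
    states, y = _prepare(matrix, k_sigma)
    relevance = _mi_columns(states, y, base)
    d = matrix.n_features
    selected: list[int] = []
    scores: list[float] = []
    red_sum = np.zeros(d)
    available = np.ones(d, dtype=bool)
    for step in range(top_n):
        if step == 0:
            step_scores = relevance.copy()
        else:
            mean_red = red_sum / step
            if scheme == "difference":
                step_scores = relevance - mean_red
            else:
                step_scores = relevance / np.maximum(mean_red, 1e-12)
        step_scores[~available] = -np.inf
        pick = int(np.argmax(step_scores))  # first max → canonical tie-break
        selected.append(pick)
        scores.append(float(step_scores[pick]))
        available[pick] = False
        if step < top_n - 1:
            red_sum += _mi_columns(states, states[:, pick], base)
    indices = np.asarray(selected)
    return RankedFeatureList(
        indices=indices,
        descriptors=[matrix.descriptors[j] for j in indices],
        scores=np.asarray(scores),
        criterion=MRMR,
    )
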