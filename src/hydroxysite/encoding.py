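"""Window → feature-vector encoding.

Each peptide window of length ``w`` (default 13, centre at position 7 in
1-based window coordinates) is encoded position by position:

* flanking positions contribute one value per usable AAindex accession
  (the index value of the residue), 20 PSSM conservation scores and one
  disorder score — ``A + 21`` features each;
* the centre position is always the same residue (P or K), so its
  AAindex values carry no information and are omitted: it contributes
  only the 20 PSSM scores and the disorder score.

With ``A`` usable indices the dimension is ``(w - 1) * (A + 21) + 21``;
the canonical AAindex release gives A = 506 and a 6,345-D space for
13-mers.  Feature order is canonical and stable: position-major, kind in
the order aaindex → pssm → disorder, sub-identifiers lexicographic.

The padding placeholder ``X`` is imputed class-neutrally: AAindex value
= mean of the index's 20 values, PSSM row = zeros, disorder = 0.5.

No feature scaling is applied by default; note that the downstream
cosine distance is scale-sensitive across features, which is a property
of the method as specified, not an oversight.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from hydroxysite.dataset import PeptideWindow, POSITIVE
from hydroxysite.io_formats import AAIndexTable, PSSM_ALPHABET

KIND_AAINDEX = "aaindex"
KIND_PSSM = "pssm"
KIND_DISORDER = "disorder"

#: PSSM column letters in canonical (lexicographic) feature order.
_PSSM_LETTERS = sorted(PSSM_ALPHABET)
_PSSM_COL = {aa: i for i, aa in enumerate(PSSM_ALPHABET)}


class FeatureDescriptor(NamedTuple):
    """Canonical identity of one feature column.

    position
        1-based window coordinate (centre = 7 for 13-mers).
    kind
        ``"aaindex"``, ``"pssm"`` or ``"disorder"``.
    sub_id
        AAindex accession, PSSM amino-acid letter, or None for disorder.
    """

    position: int
    kind: str
    sub_id: str | None

    def __str__(self) -> str:
        return f"p{self.position:02d}|{self.kind}|{self.sub_id or '-'}"

    @classmethod
    def parse(cls, text: str) -> "FeatureDescriptor":
        pos_s, kind, sub = text.split("|")
        return cls(int(pos_s[1:]), kind, None if sub == "-" else sub)


def feature_space(table: AAIndexTable, window: int = 13) -> list[FeatureDescriptor]:
    """The full ordered descriptor list for this AAindex table and window."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window length must be odd and positive")
    center = (window + 1) // 2
    descriptors: list[FeatureDescriptor] = []
    for pos in range(1, window + 1):
        if pos != center:
            for acc in table.accessions:
                descriptors.append(FeatureDescriptor(pos, KIND_AAINDEX, acc))
        for aa in _PSSM_LETTERS:
            descriptors.append(FeatureDescriptor(pos, KIND_PSSM, aa))
        descriptors.append(FeatureDescriptor(pos, KIND_DISORDER, None))
    return descriptors


def feature_space_dimensions(n_indices: int, window: int = 13) -> tuple[int, int, int]:
    """(features per flanking position, centre features, total dimension)."""
    per_flank = n_indices + 21
    center = 21
    return per_flank, center, (window - 1) * per_flank + center


def encode_window(
    window: PeptideWindow,
    table: AAIndexTable,
    descriptors: Sequence[FeatureDescriptor] | None = None,
) -> np.ndarray:
    """Encode one window into its canonical feature vector."""
    w = len(window.residues)
    if descriptors is None:
        descriptors = feature_space(table, window=w)
    vec = np.empty(len(descriptors))
    for j, d in enumerate(descriptors):
        i = d.position - 1  # window coordinate → array index
        if d.kind == KIND_AAINDEX:
            vec[j] = table.value(d.sub_id, window.residues[i])
        elif d.kind == KIND_PSSM:
            vec[j] = window.pssm_rows[i, _PSSM_COL[d.sub_id]]
        else:
            vec[j] = window.disorder[i]
    return vec


@dataclass
class FeatureMatrix:
    """Samples × named features with binary labels (1 = positive)."""

    sample_ids: list[str]
    descriptors: list[FeatureDescriptor]
    values: np.ndarray  # (n_samples, n_features)
    labels: np.ndarray  # (n_samples,) of {0, 1}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n, d = len(self.sample_ids), len(self.descriptors)
        if self.values.shape != (n, d):
            raise ValueError(f"values shape {self.values.shape} != ({n}, {d})")
        if self.labels.shape != (n,):
            raise ValueError("labels length does not match samples")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.descriptors)

    def locate(self, descriptor: FeatureDescriptor) -> int:
        """Column index of a descriptor (inverse of ``descriptors[j]``)."""
        try:
            return self._index[descriptor]
        except AttributeError:
            self._index = {d: j for j, d in enumerate(self.descriptors)}
            return self._index[descriptor]

    def to_tsv(self, path: str | Path) -> None:
        header = "sample\tlabel\t" + "\t".join(str(d) for d in self.descriptors)
        lines = [header]
        for sid, lab, row in zip(self.sample_ids, self.labels, self.values):
            cells = "\t".join(format(v, ".10g") for v in row)
            lines.append(f"{sid}\t{int(lab)}\t{cells}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        lines = Path(path).read_text().splitlines()
        header = lines[0].split("\t")
        descriptors = [FeatureDescriptor.parse(t) for t in header[2:]]
        sample_ids, labels, rows = [], [], []
        for line in lines[1:]:
            if not line.strip():
                continue
            parts = line.split("\t")
            sample_ids.append(parts[0])
            labels.append(int(parts[1]))
            rows.append([float(v) for v in parts[2:]])
        values = np.asarray(rows) if rows else np.empty((0, len(descriptors)))
        return cls(sample_ids, descriptors, values, np.asarray(labels, dtype=int))


def build_matrix(
    windows: Iterable[PeptideWindow], table: AAIndexTable, window: int = 13
) -> FeatureMatrix:
    """Encode windows into a feature matrix, preserving input order."""
    windows = list(windows)
    descriptors = feature_space(table, window=window)
    values = np.empty((len(windows), len(descriptors)))
    sample_ids: list[str] = []
    labels = np.empty(len(windows), dtype=int)
    for i, w in enumerate(windows):
        if len(w.residues) != window:
            raise ValueError(
                f"window {w.protein_id}:{w.center + 1} has length "
                f"{len(w.residues)}, expected {window}"
            )
        values[i] = encode_window(w, table, descriptors)
        sample_ids.append(f"{w.protein_id}:{w.center + 1}")
        labels[i] = int(w.label == POSITIVE)
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-finite value for sample {sample_ids[i]} at feature "
            f"{descriptors[j]}"
        )
    return FeatureMatrix(sample_ids, descriptors, values, labels)


def standardize_matrix(matrix: FeatureMatrix) -> FeatureMatrix:
    """Z-score every feature column (constant columns become zero).

    Off by default everywhere: the ranking and cosine classifier operate
    on raw feature values, and the scale sensitivity that entails is part
    of the method.  This switch exists for sensitivity analyses.
    """
    mean = matrix.values.mean(axis=0)
    std = matrix.values.std(axis=0)
    # tolerance-based: axis-wise std of a constant column can come out as
    # a few ulp rather than exactly 0
    const = std <= 1e-12 * np.maximum(1.0, np.abs(mean))
    values = (matrix.values - mean) / np.where(const, 1.0, std)
    values[:, const] = 0.0
    return FeatureMatrix(
        sample_ids=list(matrix.sample_ids),
        descriptors=list(matrix.descriptors),
        values=values,
        labels=matrix.labels.copy(),
    )


def describe_feature(
    index: int, descriptors: Sequence[FeatureDescriptor]
) -> FeatureDescriptor:
    """Descriptor of a column index (bijective with ``FeatureMatrix.locate``)."""
    if not 0 <= index < len(descriptors):
        raise IndexError(f"feature index {index} out of range 0..{len(descriptors) - 1}")
    return descriptors[index]
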