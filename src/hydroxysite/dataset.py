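"""Benchmark-dataset construction: labeled 13-residue peptide windows.

Every occurrence of the target residue (P for hydroxyproline, K for
hydroxylysine) yields one candidate window — the residue plus six
flanking residues on each side.  Windows centred on annotated
hydroxylation sites are positives; negatives are sampled uniformly
without replacement from the remaining candidates at a configurable
ratio (2:1 by default, pooled globally across proteins).

Sites too close to a terminus are either padded with the neutral
placeholder residue ``X`` (default — keeps every annotated site) or
excluded, per ``terminus_policy``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from hydroxysite.io_formats import DisorderTrack, PSSMProfile

POSITIVE = "positive"
NEGATIVE = "negative"

#: Values imputed for the padding placeholder X: a zero PSSM row and a
#: maximally uninformative disorder score.  (AAindex imputation — the
#: per-index column mean — lives in the encoding layer.)
PAD_PSSM_ROW = np.zeros(20)
PAD_DISORDER = 0.5


@dataclass
class ProteinRecord:
    """One protein with its optional profile tracks and annotated sites.

    ``positive_sites`` holds 0-based sequence positions of experimentally
    validated hydroxylation sites; each must index the target residue.
    """

    id: str
    sequence: str
    pssm: PSSMProfile | None = None
    disorder: DisorderTrack | None = None
    positive_sites: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.pssm is not None and len(self.pssm.sequence) != len(self.sequence):
            raise ValueError(f"{self.id}: PSSM length differs from sequence length")
        if self.disorder is not None and len(self.disorder) != len(self.sequence):
            raise ValueError(f"{self.id}: disorder length differs from sequence length")
        for pos in self.positive_sites:
            if not 0 <= pos < len(self.sequence):
                raise ValueError(f"{self.id}: site {pos} outside sequence")


@dataclass
class PeptideWindow:
    """A labeled window of ``2*flank + 1`` residues centred on P or K.

    ``residues`` may contain the placeholder ``X`` where the window runs
    past a protein terminus; ``pssm_rows`` and ``disorder`` are aligned
    to the window (padded positions get a zero row and 0.5)."""

    protein_id: str
    center: int  # 0-based position in the protein
    residues: str
    label: str
    pssm_rows: np.ndarray  # (window, 20)
    disorder: np.ndarray  # (window,)

    def __post_init__(self) -> None:
        w = len(self.residues)
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"label must be positive/negative, got {self.label!r}")
        self.pssm_rows = np.asarray(self.pssm_rows, dtype=float)
        self.disorder = np.asarray(self.disorder, dtype=float)
        if self.pssm_rows.shape != (w, 20):
            raise ValueError("pssm_rows shape does not match window length")
        if self.disorder.shape != (w,):
            raise ValueError("disorder length does not match window length")

    @property
    def is_positive(self) -> bool:
        return self.label == POSITIVE


def extract_windows(
    record: ProteinRecord,
    target_residue: str = "P",
    flank: int = 6,
    terminus_policy: str = "pad",
) -> list[PeptideWindow]:
    """One candidate window per occurrence of ``target_residue``.

    Windows are labeled positive when the centre is in
    ``record.positive_sites``.  Near a terminus, ``terminus_policy``
    chooses between ``"pad"`` (placeholder X, default) and ``"exclude"``
    (drop the window).
    """
    if target_residue not in ("P", "K"):
        raise ValueError("target residue must be P or K")
    if terminus_policy not in ("pad", "exclude"):
        raise ValueError(f"unknown terminus policy {terminus_policy!r}")
    seq = record.sequence
    length = len(seq)
    windows: list[PeptideWindow] = []
    for center in range(length):
        if seq[center] != target_residue:
            continue
        lo, hi = center - flank, center + flank  # inclusive window bounds
        if (lo < 0 or hi >= length) and terminus_policy == "exclude":
            continue
        residues: list[str] = []
        pssm_rows = np.zeros((2 * flank + 1, 20))
        disorder = np.full(2 * flank + 1, PAD_DISORDER)
        for k, pos in enumerate(range(lo, hi + 1)):
            if 0 <= pos < length:
                residues.append(seq[pos])
                if record.pssm is not None:
                    pssm_rows[k] = record.pssm.row(pos)
                if record.disorder is not None:
                    disorder[k] = record.disorder.scores[pos]
            else:
                residues.append("X")
                pssm_rows[k] = PAD_PSSM_ROW
                disorder[k] = PAD_DISORDER
        label = POSITIVE if center in record.positive_sites else NEGATIVE
        windows.append(
            PeptideWindow(
                protein_id=record.id,
                center=center,
                residues="".join(residues),
                label=label,
                pssm_rows=pssm_rows,
                disorder=disorder,
            )
        )
    return windows


def sample_negatives(
    candidates: Sequence[PeptideWindow],
    n_positive: int,
    ratio: float = 2.0,
    seed: int = 0,
) -> list[PeptideWindow]:
    """Draw ``round(ratio * n_positive)`` negatives uniformly without
    replacement; deterministic given ``seed``."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    n_wanted = round(ratio * n_positive)
    if any(w.is_positive for w in candidates):
        raise ValueError("candidate pool contains positive windows")
    if n_wanted > len(candidates):
        raise ValueError(
            f"need {n_wanted} negatives but only {len(candidates)} candidates "
            f"(shortfall {n_wanted - len(candidates)})"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=n_wanted, replace=False)
    return [candidates[i] for i in np.sort(idx)]


def build_dataset(
    records: Iterable[ProteinRecord],
    target_residue: str = "P",
    ratio: float = 2.0,
    seed: int = 0,
    flank: int = 6,
    terminus_policy: str = "pad",
) -> list[PeptideWindow]:
    """Extract windows from all proteins and assemble the benchmark set:
    every positive plus negatives sampled globally at ``ratio``:1."""
    positives: list[PeptideWindow] = []
    negatives: list[PeptideWindow] = []
    for record in records:
        for w in extract_windows(record, target_residue, flank, terminus_policy):
            (positives if w.is_positive else negatives).append(w)
    sampled = sample_negatives(negatives, len(positives), ratio=ratio, seed=seed)
    return positives + sampled


# ---------------------------------------------------------------------------
# Peptide tables (supplementary-table-style TSV)
# ---------------------------------------------------------------------------


def write_peptide_table(windows: Iterable[PeptideWindow], path: str | Path) -> None:
    """TSV of (peptide string, protein id, 1-based centre position, label)."""
    lines = ["peptide\tprotein\tposition\tlabel"]
    for w in windows:
        lines.append(f"{w.residues}\t{w.protein_id}\t{w.center + 1}\t{w.label}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_peptide_table(path: str | Path) -> list[tuple[str, str, int, str]]:
    """Parse a peptide table back to (peptide, protein, 0-based centre, label)."""
    rows: list[tuple[str, str, int, str]] = []
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 fields")
        peptide, protein, pos_s, label = parts
        rows.append((peptide, protein, int(pos_s) - 1, label))
    return rows
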