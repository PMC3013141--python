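"""Readers and writers for every external file format the pipeline touches.

Formats handled here:

* AAindex1 flat files (numerical amino-acid property indices),
* PSI-BLAST ASCII PSSM dumps (``-out_ascii_pssm`` style),
* per-residue intrinsic-disorder tracks (TSV: position, score),
* annotated modification-site tables (TSV: protein id, position, residue),
* FASTA sequence files (delegated to Biopython).

Positions are 1-based in all external files and 0-based everywhere in
memory; the converters in this module are the only place the shift
happens.  Every reader has a matching writer and ``read(write(x)) == x``
on valid in-memory objects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: One-letter amino-acid codes in alphabetical order; the canonical key
#: order for AAindex vectors held in memory.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Column order of the 20 scores in a PSI-BLAST ASCII PSSM.
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

# Row layout of the value lines in an AAindex1 record: the ``I`` section
# holds two lines of ten values, column-paired as A/L, R/K, ... I/V.
_AAINDEX_ROW1 = "ARNDCQEGHI"
_AAINDEX_ROW2 = "LKMFPSTWYV"

#: The five property clusters AAindex accessions are conventionally
#: grouped into, plus the fallback for unmapped accessions.
AAINDEX_CLUSTERS = (
    "alpha-and-turn-propensities",
    "beta-propensity",
    "composition",
    "hydrophobicity",
    "physicochemical",
)
UNASSIGNED_CLUSTER = "unassigned"


class ParseError(ValueError):
    """A file did not follow its expected grammar."""


# ---------------------------------------------------------------------------
# AAindex
# ---------------------------------------------------------------------------


@dataclass
class AAIndexTable:
    """A set of amino-acid property indices.

    Parameters
    ----------
    entries
        Maps an index accession (e.g. ``"KYTJ820101"``) to a vector of 20
        finite values ordered like :data:`AA_ALPHABET`.
    clusters
        Maps an accession to one of the five property clusters; accessions
        absent here are reported as ``"unassigned"``.
    """

    entries: dict[str, np.ndarray] = field(default_factory=dict)
    clusters: dict[str, str] = field(default_factory=dict)

    @property
    def count(self) -> int:
        return len(self.entries)

    @property
    def accessions(self) -> list[str]:
        """Accessions in sorted (canonical) order."""
        return sorted(self.entries)

    def value(self, accession: str, residue: str) -> float:
        """Index value for one residue; the column mean for placeholder X."""
        vec = self.entries[accession]
        if residue == "X":
            return float(vec.mean())
        return float(vec[AA_ALPHABET.index(residue)])

    def cluster_of(self, accession: str) -> str:
        return self.clusters.get(accession, UNASSIGNED_CLUSTER)


def read_aaindex(path: str | Path, drop_na: bool = True) -> AAIndexTable:
    """Parse an AAindex1 flat file.

    Records are delimited by ``//``; the accession comes from the ``H``
    line and the 20 values from the two lines following the ``I`` header.
    Indices containing any ``NA`` value are excluded when ``drop_na`` is
    true (the exclusion count is logged); otherwise they raise.
    """
    text = Path(path).read_text()
    table = AAIndexTable()
    dropped = 0
    for raw in text.split("//"):
        record = raw.strip("\n")
        if not record.strip():
            continue
        accession = None
        values: list[float] | None = None
        has_na = False
        lines = record.split("\n")
        for i, line in enumerate(lines):
            if line.startswith("H "):
                accession = line[2:].strip()
            elif line.startswith("I "):
                tokens: list[str] = []
                for vline in lines[i + 1 : i + 3]:
                    tokens.extend(vline.split())
                if len(tokens) != 20:
                    raise ParseError(
                        f"AAindex record {accession or '<no H line>'}: "
                        f"expected 20 values after the I line, got {len(tokens)}"
                    )
                if any(t.upper() == "NA" for t in tokens):
                    has_na = True
                    break
                row1 = tokens[:10]  # A R N D C Q E G H I
                row2 = tokens[10:]  # L K M F P S T W Y V
                by_aa = dict(zip(_AAINDEX_ROW1, row1)) | dict(zip(_AAINDEX_ROW2, row2))
                values = [float(by_aa[aa]) for aa in AA_ALPHABET]
                break
        if accession is None:
            raise ParseError("AAindex record without an H (accession) line")
        if has_na:
            if drop_na:
                dropped += 1
                continue
            raise ParseError(f"AAindex record {accession} contains NA values")
        if values is None:
            raise ParseError(f"AAindex record {accession}: missing I line")
        vec = np.asarray(values, dtype=float)
        if not np.all(np.isfinite(vec)):
            raise ParseError(f"AAindex record {accession}: non-finite values")
        table.entries[accession] = vec
    if dropped:
        logger.info("read_aaindex: excluded %d indices containing NA", dropped)
    return table


def write_aaindex(table: AAIndexTable, path: str | Path) -> None:
    """Write entries back out in AAindex1 record grammar."""
    lines: list[str] = []
    for acc in table.accessions:
        vec = table.entries[acc]
        by_aa = dict(zip(AA_ALPHABET, vec))
        lines.append(f"H {acc}")
        lines.append("D synthetic or re-serialized amino acid index")
        lines.append(
            "I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V"
        )
        lines.append("  " + " ".join(f"{by_aa[aa]:8.3f}" for aa in _AAINDEX_ROW1))
        lines.append("  " + " ".join(f"{by_aa[aa]:8.3f}" for aa in _AAINDEX_ROW2))
        lines.append("//")
    Path(path).write_text("\n".join(lines) + "\n")


def read_cluster_map(path: str | Path) -> dict[str, str]:
    """Read an accession → property-cluster mapping (two-column TSV)."""
    clusters: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 tab-separated fields")
        clusters[parts[0]] = parts[1]
    return clusters


def write_cluster_map(clusters: dict[str, str], path: str | Path) -> None:
    lines = [f"{acc}\t{cl}" for acc, cl in sorted(clusters.items())]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PSSM
# ---------------------------------------------------------------------------


@dataclass
class PSSMProfile:
    """A position-specific scoring matrix for one protein.

    ``scores`` has one row per residue and 20 columns ordered like
    :data:`PSSM_ALPHABET` (the column order PSI-BLAST emits).
    """

    sequence: str
    scores: np.ndarray  # (L, 20)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.sequence), 20):
            raise ValueError(
                f"PSSM shape {self.scores.shape} does not match sequence "
                f"length {len(self.sequence)}"
            )

    def row(self, position: int) -> np.ndarray:
        """Scores of the residue at 0-based ``position``."""
        return self.scores[position]


def read_pssm(path: str | Path, block: str = "log_odds") -> PSSMProfile:
    """Parse a PSI-BLAST ASCII PSSM dump.

    Each data row carries the position, the residue letter, 20 log-odds
    scores and 20 weighted-percentage columns.  ``block`` selects which
    20-column block to keep: ``"log_odds"`` (default, the conventional
    conservation encoding) or ``"percent"``.
    """
    if block not in ("log_odds", "percent"):
        raise ValueError(f"unknown PSSM block {block!r}")
    residues: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        parts = line.split()
        if len(parts) < 2 or not parts[0].isdigit():
            continue  # header, separator or footer (lambda/K statistics)
        numeric = parts[2:]
        if len(numeric) not in (40, 42):  # 42 = trailing information/weight columns
            raise ParseError(
                f"{path}:{lineno}: expected 40 score columns, found {len(numeric)}"
            )
        try:
            vals = [float(v) for v in numeric[:40]]
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric score column: {exc}") from None
        residues.append(parts[1])
        rows.append(vals[:20] if block == "log_odds" else vals[20:40])
    if not rows:
        raise ParseError(f"{path}: no PSSM data rows found")
    return PSSMProfile(sequence="".join(residues), scores=np.asarray(rows))


def write_pssm(profile: PSSMProfile, path: str | Path, percent: np.ndarray | None = None) -> None:
    """Write a profile in PSI-BLAST ASCII layout (both 20-column blocks).

    When ``percent`` is not given the percentage block is filled with
    zeros; round-tripping the default log-odds block is exact.
    """
    if percent is None:
        percent = np.zeros_like(profile.scores)
    header = "  ".join(PSSM_ALPHABET)
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed percentages rounded down, information per position, and relative weight of gapless real matches to pseudocounts",
        f"            {header}   {header}",
    ]
    for i, (aa, row, prow) in enumerate(
        zip(profile.sequence, profile.scores, percent), start=1
    ):
        cells = " ".join(f"{v:6.0f}" if float(v).is_integer() else f"{v:6.2f}" for v in row)
        pcells = " ".join(f"{v:4.0f}" for v in prow)
        lines.append(f"{i:5d} {aa}  {cells}   {pcells}")
    lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Disorder tracks
# ---------------------------------------------------------------------------


@dataclass
class DisorderTrack:
    """Per-residue intrinsic-disorder scores, each in [0, 1]."""

    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1:
            raise ValueError("disorder track must be one-dimensional")
        if np.any((self.scores < 0) | (self.scores > 1)):
            bad = np.flatnonzero((self.scores < 0) | (self.scores > 1))
            raise ValueError(
                f"disorder scores outside [0, 1] at 0-based positions {bad.tolist()}"
            )

    def __len__(self) -> int:
        return len(self.scores)


def read_disorder(path: str | Path) -> DisorderTrack:
    """Read a two-column TSV (1-based position, score in [0, 1])."""
    scores: list[float] = []
    expected = 1
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 tab-separated fields")
        pos = int(parts[0])
        if pos != expected:
            raise ParseError(
                f"{path}:{lineno}: positions must be contiguous from 1; "
                f"expected {expected}, got {pos}"
            )
        scores.append(float(parts[1]))
        expected += 1
    return DisorderTrack(scores=np.asarray(scores))


def write_disorder(track: DisorderTrack, path: str | Path) -> None:
    lines = [f"{i}\t{s:.4f}" for i, s in enumerate(track.scores, start=1)]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Site tables
# ---------------------------------------------------------------------------


def read_sites(path: str | Path) -> list[tuple[str, int, str]]:
    """Read an annotated-site table: TSV of (protein id, 1-based position,
    residue letter).  Validation against sequences is a separate step
    (:func:`validate_sites`) because the FASTA may not be at hand."""
    sites: list[tuple[str, int, str]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 3:
            raise ParseError(f"{path}:{lineno}: expected 3 tab-separated fields")
        pid, pos_s, residue = parts
        pos = int(pos_s)
        if pos < 1:
            raise ParseError(f"{path}:{lineno}: positions are 1-based; got {pos}")
        sites.append((pid, pos, residue))
    return sites


def write_sites(sites: Iterable[tuple[str, int, str]], path: str | Path) -> None:
    lines = [f"{pid}\t{pos}\t{res}" for pid, pos, res in sites]
    Path(path).write_text("\n".join(lines) + "\n")


def validate_sites(
    sites: Iterable[tuple[str, int, str]], sequences: dict[str, str]
) -> None:
    """Cross-check site annotations against their sequences.

    Raises a single :class:`ValueError` listing every offender: unknown
    protein ids, positions beyond the sequence length, and residue
    letters that disagree with the sequence.
    """
    problems: list[str] = []
    for pid, pos, residue in sites:
        if pid not in sequences:
            problems.append(f"{pid}:{pos}: unknown protein id")
            continue
        seq = sequences[pid]
        if pos > len(seq):
            problems.append(f"{pid}:{pos}: beyond sequence length {len(seq)}")
        elif seq[pos - 1] != residue:
            problems.append(
                f"{pid}:{pos}: annotated {residue} but sequence has {seq[pos - 1]}"
            )
    if problems:
        raise ValueError("invalid site annotations: " + "; ".join(problems))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Sequences keyed by record id, in file order."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
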