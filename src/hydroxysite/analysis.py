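"""Feature-distribution analyses of selected feature sets.

Given a selected feature set (e.g. the top-500 MaxRel list, or the
IFS-optimal prefix) and the descriptor universe it was drawn from, these
tables compare the *distributive* frequency — the count expected if the
set were drawn proportionally from the universe — with the *resultant*
(observed) count, broken down by feature kind, window position, AAindex
property cluster, and PSSM amino-acid column.  A kind (or position,
cluster, column) whose resultant count exceeds its distributive
frequency is over-represented among the discriminative features.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from hydroxysite.encoding import (
    FeatureDescriptor,
    KIND_AAINDEX,
    KIND_DISORDER,
    KIND_PSSM,
)
from hydroxysite.io_formats import AAIndexTable, AAINDEX_CLUSTERS, UNASSIGNED_CLUSTER

_KINDS = (KIND_AAINDEX, KIND_PSSM, KIND_DISORDER)


def kind_distribution(
    features: Sequence[FeatureDescriptor],
    background: Sequence[FeatureDescriptor],
) -> pd.DataFrame:
    """Distributive vs resultant counts of the three feature kinds.

    ``distributive`` is the background proportion of the kind times the
    selected-set size (a real number; it sums to the set size), and
    ``resultant`` the observed count (an integer partition of the set).
    """
    if not set(features) <= set(background):
        raise ValueError("selected features must be drawn from the background")
    n = len(features)
    total = len(background)
    rows = []
    for kind in _KINDS:
        bg = sum(1 for d in background if d.kind == kind)
        obs = sum(1 for d in features if d.kind == kind)
        rows.append(
            {
                "kind": kind,
                "background_count": bg,
                "distributive": bg / total * n if total else 0.0,
                "resultant": obs,
                "resultant_proportion": obs / n if n else 0.0,
            }
        )
    return pd.DataFrame(rows)


def position_distribution(
    features: Sequence[FeatureDescriptor], window: int = 13
) -> pd.DataFrame:
    """Counts of selected features per window position 1..window.

    The centre position carries only PSSM/disorder features by
    construction; it is flagged so the table cannot be misread as the
    centre lacking discriminative amino-acid properties.
    """
    center = (window + 1) // 2
    counts = {pos: 0 for pos in range(1, window + 1)}
    for d in features:
        if not 1 <= d.position <= window:
            raise ValueError(f"feature {d} outside window 1..{window}")
        counts[d.position] += 1
    n = len(features)
    return pd.DataFrame(
        {
            "position": list(counts),
            "count": list(counts.values()),
            "proportion": [c / n if n else 0.0 for c in counts.values()],
            "note": [
                "pssm/disorder-only (centre)" if pos == center else ""
                for pos in counts
            ],
        }
    )


def cluster_distribution(
    features: Sequence[FeatureDescriptor], table: AAIndexTable
) -> pd.DataFrame:
    """Counts of the AAindex subset of features per property cluster.

    Accessions without a cluster assignment are tallied under
    ``"unassigned"`` rather than dropped, so the counts always partition
    the AAindex subset.
    """
    order = list(AAINDEX_CLUSTERS) + [UNASSIGNED_CLUSTER]
    counts = {cl: 0 for cl in order}
    for d in features:
        if d.kind != KIND_AAINDEX:
            continue
        cl = table.cluster_of(d.sub_id)
        if cl not in counts:
            counts[cl] = 0
            order.append(cl)
        counts[cl] += 1
    return pd.DataFrame({"cluster": order, "count": [counts[cl] for cl in order]})


def pssm_column_distribution(
    features: Sequence[FeatureDescriptor],
) -> pd.DataFrame:
    """Counts of the PSSM subset of features per amino-acid column."""
    letters = sorted("ARNDCQEGHILKMFPSTWYV")
    counts = {aa: 0 for aa in letters}
    for d in features:
        if d.kind == KIND_PSSM:
            counts[d.sub_id] += 1
    return pd.DataFrame(
        {"amino_acid": letters, "count": [counts[aa] for aa in letters]}
    )


def plot_distribution(
    frame: pd.DataFrame, x: str, y: str | list[str], path: str | Path, title: str = ""
) -> None:
    """Render one distribution table as a bar chart (PNG/SVG by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ax = frame.plot.bar(x=x, y=y, rot=0, figsize=(8, 4), legend=isinstance(y, list))
    ax.set_title(title)
    ax.figure.tight_layout()
    ax.figure.savefig(str(path))
    plt.close(ax.figure)
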