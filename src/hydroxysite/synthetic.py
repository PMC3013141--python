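"""Synthetic fixtures with planted ground truth.

The generator emits desk-scale versions of every input the pipeline
consumes — FASTA sequences, a site table, per-protein PSSM files,
disorder tracks and a miniature AAindex table — with a known set of
class-discriminative features planted, so that feature ranking and
selection can be scored against ground truth without any downloads.

Construction: target residues are placed on a regular grid spaced one
window apart, so candidate windows never overlap and each residue's
profile values belong to exactly one window.  Flanking residues are
drawn from the 19 non-target amino acids, so no spurious candidate
windows arise.  The class signal is planted at the feature level: for
each of ``n_informative_features`` descriptors chosen among the PSSM and
disorder features, the corresponding profile value in positive windows
is shifted by ``effect_size`` within-class standard deviations.  AAindex
features react only to the (random) flanking residues and are therefore
pure noise — they play the role of the uninformative bulk of the
feature space.  With ``effect_size = 0`` the two classes are identically
distributed and jackknife accuracy sits at chance.

This emulates the statistical structure of the task (a few informative
profile features among thousands of noise features), not collagen
biology.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from hydroxysite.dataset import ProteinRecord, build_dataset
from hydroxysite.encoding import (
    FeatureDescriptor,
    FeatureMatrix,
    KIND_DISORDER,
    KIND_PSSM,
    build_matrix,
)
from hydroxysite.io_formats import (
    AAIndexTable,
    AAINDEX_CLUSTERS,
    AA_ALPHABET,
    DisorderTrack,
    PSSM_ALPHABET,
    PSSMProfile,
    write_aaindex,
    write_cluster_map,
    write_disorder,
    write_fasta,
    write_pssm,
    write_sites,
)

# Background distributions of the profile tracks.  PSSM scores mimic
# integer log-odds (slightly negative on average); disorder scores sit
# in mid-range with room to shift upward without saturating [0, 1].
_PSSM_MEAN, _PSSM_SD = -1.0, 2.0
_DIS_MEAN, _DIS_SD = 0.3, 0.1


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic benchmark.

    ``effect_size`` is the mean shift of each planted feature between
    classes, in units of the within-class standard deviation.
    """

    seed: int
    n_proteins: int = 10
    seq_length: int = 260
    n_positive_sites: int = 65
    target_residue: str = "P"
    n_informative_features: int = 10
    effect_size: float = 3.0
    n_aaindex: int = 8
    flank: int = 6

    def __post_init__(self) -> None:
        window = 2 * self.flank + 1
        if self.seq_length < window:
            raise ValueError(
                f"seq_length must be at least the window length {window}"
            )
        for name in (
            "n_proteins",
            "n_positive_sites",
            "n_informative_features",
            "n_aaindex",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.target_residue not in ("P", "K"):
            raise ValueError("target residue must be P or K")

    @property
    def window(self) -> int:
        return 2 * self.flank + 1

    def site_grid(self) -> list[int]:
        """0-based centre positions of candidate sites in one protein."""
        return list(range(self.flank, self.seq_length - self.flank, self.window))


def _mini_aaindex(rng: np.random.Generator, n_indices: int) -> AAIndexTable:
    table = AAIndexTable()
    for i in range(n_indices):
        acc = f"SYNI{i + 1:04d}"
        table.entries[acc] = np.round(rng.normal(0.0, 1.0, size=20), 3)
        table.clusters[acc] = AAINDEX_CLUSTERS[i % len(AAINDEX_CLUSTERS)]
    return table


def _planted_descriptors(
    rng: np.random.Generator, spec: SyntheticSpec
) -> list[FeatureDescriptor]:
    pool: list[FeatureDescriptor] = []
    for pos in range(1, spec.window + 1):
        for aa in sorted(PSSM_ALPHABET):
            pool.append(FeatureDescriptor(pos, KIND_PSSM, aa))
        pool.append(FeatureDescriptor(pos, KIND_DISORDER, None))
    if spec.n_informative_features > len(pool):
        raise ValueError(
            f"cannot plant {spec.n_informative_features} features in a pool of {len(pool)}"
        )
    picks = rng.choice(len(pool), size=spec.n_informative_features, replace=False)
    return [pool[i] for i in np.sort(picks)]


def generate(
    spec: SyntheticSpec,
) -> tuple[list[ProteinRecord], list[FeatureDescriptor], AAIndexTable]:
    """Generate protein records with planted discriminative features.

    Returns the records (sequence + PSSM + disorder + positive sites),
    the ground-truth descriptor set, and the miniature AAindex table.
    Everything is a deterministic function of ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    table = _mini_aaindex(rng, spec.n_aaindex)
    truth = _planted_descriptors(rng, spec)

    grid = spec.site_grid()
    n_slots = spec.n_proteins * len(grid)
    if spec.n_positive_sites >= n_slots:
        raise ValueError(
            f"{spec.n_positive_sites} positive sites requested but only "
            f"{n_slots} candidate sites exist"
        )
    positive_slots = set(
        rng.choice(n_slots, size=spec.n_positive_sites, replace=False).tolist()
    )

    flank_alphabet = [aa for aa in AA_ALPHABET if aa != spec.target_residue and aa != "X"]
    pssm_col = {aa: i for i, aa in enumerate(PSSM_ALPHABET)}
    records: list[ProteinRecord] = []
    slot = 0
    for p in range(spec.n_proteins):
        letters = rng.choice(list(flank_alphabet), size=spec.seq_length)
        seq = list("".join(letters))
        for c in grid:
            seq[c] = spec.target_residue
        scores = np.round(
            rng.normal(_PSSM_MEAN, _PSSM_SD, size=(spec.seq_length, 20))
        )
        disorder = np.clip(
            np.round(rng.normal(_DIS_MEAN, _DIS_SD, size=spec.seq_length), 4),
            0.0,
            1.0,
        )
        positive_sites: set[int] = set()
        for c in grid:
            is_positive = slot in positive_slots
            if is_positive:
                positive_sites.add(c)
                for d in truth:
                    pos = c + (d.position - (spec.flank + 1))
                    if d.kind == KIND_PSSM:
                        scores[pos, pssm_col[d.sub_id]] = np.round(
                            rng.normal(
                                _PSSM_MEAN + spec.effect_size * _PSSM_SD, _PSSM_SD
                            )
                        )
                    else:
                        disorder[pos] = np.clip(
                            np.round(
                                rng.normal(
                                    _DIS_MEAN + spec.effect_size * _DIS_SD, _DIS_SD
                                ),
                                4,
                            ),
                            0.0,
                            1.0,
                        )
            else:
                # burn the same number of draws so slot labels do not
                # shift the random stream of later proteins
                for d in truth:
                    rng.normal()
            slot += 1
        records.append(
            ProteinRecord(
                id=f"synprot{p + 1:03d}",
                sequence="".join(seq),
                pssm=PSSMProfile(sequence="".join(seq), scores=scores),
                disorder=DisorderTrack(scores=disorder),
                positive_sites=positive_sites,
            )
        )
    return records, truth, table


def benchmark_matrix(
    spec: SyntheticSpec, ratio: float = 2.0
) -> tuple[FeatureMatrix, list[FeatureDescriptor], AAIndexTable]:
    """Full synthetic benchmark: generate, window, sample and encode.

    Negatives are sampled at ``ratio``:1 with a seed derived from the
    spec seed, so the whole benchmark is one deterministic function of
    ``spec``.
    """
    records, truth, table = generate(spec)
    windows = build_dataset(
        records,
        target_residue=spec.target_residue,
        ratio=ratio,
        seed=spec.seed + 1,
        flank=spec.flank,
    )
    return build_matrix(windows, table, window=spec.window), truth, table


def write_fixtures(spec: SyntheticSpec, outdir: str | Path) -> dict[str, Path]:
    """Write the generated data as on-disk fixtures in every pipeline
    input format.  Byte-identical for identical specs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "pssm").mkdir(exist_ok=True)
    (outdir / "disorder").mkdir(exist_ok=True)
    records, truth, table = generate(spec)

    paths = {
        "fasta": outdir / "proteins.fasta",
        "sites": outdir / "sites.tsv",
        "aaindex": outdir / "aaindex.txt",
        "clusters": outdir / "clusters.tsv",
        "truth": outdir / "planted_features.txt",
    }
    write_fasta({r.id: r.sequence for r in records}, paths["fasta"])
    sites = [
        (r.id, pos + 1, r.sequence[pos])
        for r in records
        for pos in sorted(r.positive_sites)
    ]
    write_sites(sites, paths["sites"])
    write_aaindex(table, paths["aaindex"])
    write_cluster_map(table.clusters, paths["clusters"])
    paths["truth"].write_text("\n".join(str(d) for d in truth) + "\n")
    for r in records:
        write_pssm(r.pssm, outdir / "pssm" / f"{r.id}.pssm")
        write_disorder(r.disorder, outdir / "disorder" / f"{r.id}.tsv")
    return paths
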