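# hydroxysite

Sequence-based prediction and analysis of protein hydroxylation sites
(hydroxyproline and hydroxylysine).

Hydroxylation of proline (at Cγ) and lysine (at Cδ) is a post-translational
modification central to collagen stability and to hypoxia signalling.
Experimental mapping of hydroxylation sites by mass spectrometry is slow and
expensive; `hydroxysite` implements an in-silico predictor that decides, for
every proline or lysine in a protein, whether it is a likely hydroxylation
site, and analyses which sequence features carry the signal.

## Method

Each candidate residue is represented by a 13-residue window (the site plus
six residues on either side). Every window position is encoded with three
kinds of features:

- **AAindex** — one value per usable amino-acid property index (A = 506 in
  the canonical AAindex1 release after dropping indices with missing values);
- **PSSM conservation** — the 20 log-odds scores of the residue's row in a
  PSI-BLAST position-specific scoring matrix;
- **intrinsic disorder** — a per-residue disorder score in [0, 1] (e.g. from
  VSL2).

The centre residue is always P (or K), so its AAindex values are constant and
omitted: flanking positions contribute A + 21 features each and the centre 21,
giving a 12 × (A + 21) + 21 = 6,345-dimensional space at A = 506.

Features are ranked by mutual information: **MaxRel** sorts by relevance
I(f; class), and **mRMR** greedily selects features maximizing relevance minus
mean redundancy with the already-selected set (MID scheme; MIQ available),
computed on a three-state mean ± σ discretization.

Classification uses a **nearest-neighbour** rule under the cosine distance

    D(u, v) = 1 − (u · v) / (‖u‖ ‖v‖),

evaluated by **jackknife** (leave-one-out) cross-validation and summarized as
sensitivity Sn = TP/(TP+FN), specificity Sp = TN/(TN+FP), accuracy
AC = (TP+TN)/n and the Matthews correlation coefficient MCC.
**Incremental feature selection (IFS)** evaluates the nested prefixes
S₁ ⊂ S₂ ⊂ … of the mRMR list and selects the prefix at the peak of the
accuracy curve as the final model.

Positive examples are annotated hydroxylation sites; negatives are drawn
uniformly without replacement from the remaining P/K windows at 2:1.

The package consumes sequences (FASTA), site annotations (TSV), PSI-BLAST
ASCII PSSM files, per-residue disorder tracks (TSV) and the AAindex1 flat
file. Running PSI-BLAST or a disorder predictor, and querying sequence
databases, are outside its scope. A synthetic-fixture generator with planted
ground-truth features makes every stage testable offline.

## Worked example

Generate a small synthetic benchmark (4 proteins, 12 planted positive sites,
10 informative features at 3 SD effect) and run the full pipeline:

```sh
hydroxysite make-fixtures --outdir fx --seed 11 --n-proteins 4 \
    --seq-length 130 --n-positive-sites 12 --n-aaindex 4
hydroxysite build-dataset --fasta fx/proteins.fasta --sites fx/sites.tsv \
    --pssm-dir fx/pssm --disorder-dir fx/disorder --ratio 2 --seed 12 \
    --out windows.tsv
hydroxysite encode --windows windows.tsv --fasta fx/proteins.fasta \
    --pssm-dir fx/pssm --disorder-dir fx/disorder --aaindex fx/aaindex.txt \
    --out matrix.tsv
hydroxysite rank --matrix matrix.tsv --criterion mrmr --top-n 25 --out ranked.tsv
hydroxysite ifs --matrix matrix.tsv --ranked ranked.tsv --max-k 25 \
    --out curve.tsv --model-out model.json
```

which prints:

```
wrote fixtures to fx (5 top-level files)
wrote 36 windows (12 positive) to windows.tsv
wrote 36×321 matrix to matrix.tsv
wrote 25-feature mrmr list to ranked.tsv
IFS optimum at k=3: Sn=1.000 Sp=1.000 AC=1.000 MCC=1.000
```

36 windows are the 12 positives plus 24 sampled negatives; 321 features is
12 × (4 + 21) + 21 for the 4-index miniature AAindex. The ranked list starts
with planted features (`p13|pssm|I` reads: PSSM column I at window position
13), and the IFS curve rises to its peak at k = 3 features, where the
jackknife classifies every window correctly:

```
k	Sn	Sp	AC	MCC
1	1.000000	0.500000	0.666667	0.500000
2	0.916667	0.916667	0.916667	0.817861
3	1.000000	1.000000	1.000000	1.000000
```

`hydroxysite predict` applies the serialized optimal model to new
FASTA + PSSM + disorder inputs, and `hydroxysite analyze` writes the
feature-distribution tables (kind, window position, AAindex property cluster,
PSSM amino-acid column; expected vs observed counts) for any ranked list.

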