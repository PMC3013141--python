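# Methods

## Problem and model

The package classifies 13-residue peptide windows centred on proline or
lysine as hydroxylated or not. The classification unit is the window, not
the protein: a protein contributes one sample per candidate residue.
Three information sources are encoded per window position — amino-acid
physicochemical properties (AAindex), evolutionary conservation (PSI-BLAST
PSSM log-odds) and intrinsic disorder — on the premise that hydroxylases
recognise local sequence context, that modified positions are conserved,
and that modifications often fall in flexible regions.

The classifier is deliberately minimal: a 1-nearest-neighbour rule under
the cosine distance D(u, v) = 1 − cos(u, v). Its capacity is controlled
entirely by feature selection: mutual-information ranking (MaxRel/mRMR)
followed by incremental feature selection (IFS), which evaluates every
nested prefix of the ranked list by jackknife and keeps the prefix at the
accuracy peak.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| window length | 13 (6+1+6) | classification unit; odd, centre = position 7 |
| negative:positive ratio | 2.0 | negatives drawn uniformly without replacement, pooled across proteins |
| terminus policy | `pad` | windows crossing a terminus are padded with placeholder X (`exclude` drops them) |
| PSSM block | log-odds | the ASCII PSSM's first 20-column block; weighted percentages selectable |
| discretization | mean ± 1·σ, 3 states | per-feature, before any mutual information; constant features → middle state |
| MI base | 2 (bits) | fixed and recorded in output manifests |
| mRMR scheme | difference (MID) | quotient (MIQ) available |
| ranked-list length | 500 | `top_n` of the rank stage |
| IFS objective | accuracy | MCC selectable; ties resolve to the smallest k |

Defaults that the method's description leaves open (which PSSM block,
discretization constant, MID vs MIQ, MI base, terminus handling) are fixed
to the conventional choices above and are all configurable; none is
derivable from first principles, so each is an explicit assumption of this
implementation.

AAindex releases contain more indices than are usable; indices with any
missing (NA) value are dropped at parse time and the count is recorded —
the dimension formula 12 × (A + 21) + 21 always uses the realized A, never
a hard-coded constant. Property-cluster labels for accessions are supplied
by an external accession→cluster TSV; no curated mapping ships with the
package, and unmapped accessions are tallied as "unassigned" in the
cluster-distribution analysis rather than dropped.

## Numerical and degenerate-case choices

- **Zero-norm vectors.** The cosine distance between two explicit vectors
  (`nna_distance`, `nna_predict`) raises on a zero-norm input, since the
  quantity is undefined. Inside jackknife/IFS, however, restricting
  samples to a small feature prefix routinely produces zero vectors (a
  single PSSM feature with score 0), so the evaluation loop uses a
  documented convention by default: a zero-norm sample has cosine
  similarity 0 — distance 1 — to everything, i.e. it carries no
  directional information. Strict behaviour is available via
  `zero_norm="error"`.
- **Nearest-neighbour ties** break to the lowest training-sample index;
  **IFS peak ties** to the smallest k; **MI ranking ties** to the canonical
  feature order. All outputs are therefore bit-reproducible.
- **MCC with a zero denominator** (a degenerate confusion margin) is
  defined as 0 and logged; an empty class's success rate is reported as 0.
- **Placeholder residue X** (terminus padding) is imputed class-neutrally:
  AAindex value = the index's 20-value mean, PSSM row = zeros,
  disorder = 0.5.
- **No feature scaling** is applied before ranking or classification. The
  cosine distance is scale-sensitive across features of different kinds;
  this mirrors the method as published and is preserved, not corrected. A
  standardization switch exists but defaults off.
- The IFS loop accumulates pairwise dot products incrementally
  (O(n²) per k rather than O(n²k)); a test pins it to de-novo jackknife
  at every k.

## Synthetic benchmark

The generator emulates the statistical structure of the task, not collagen
biology. Target residues are placed on a grid spaced one window apart, so
candidate windows never overlap and each residue's profile values belong
to exactly one window; flanking residues are drawn from the 19 non-target
amino acids, so no unintended candidates arise. The class signal is
planted at the feature level: `n_informative_features` descriptors chosen
among the PSSM and disorder features are shifted in positive windows by
`effect_size` within-class standard deviations. AAindex features respond
only to the random flanking residues and form the uninformative bulk of
the space.

Default study conditions: 10 proteins of length 260 → 200 candidate
sites, 65 positives, negatives sampled 2:1 → 195 samples; 10 planted
features at effect 3 SD; an 8-index miniature AAindex table → a 369-D
space. These sizes keep a 20-replicate recovery experiment at desk scale
while leaving the planted features a small minority of the space.
Backgrounds: PSSM scores are rounded N(−1, 2) (integer log-odds, slightly
negative on average, so windows of each class have a consistent
orientation under the cosine distance); disorder is N(0.3, 0.1) clipped to
[0, 1], leaving headroom for upward shifts without saturation.

What passing the synthetic gates shows: the pipeline recovers planted
discriminative features through encoding, discretization, mRMR and IFS,
and its accuracy estimates respond to real signal (and collapse to chance
at effect 0). What it does not show: performance on real proteins, where
features are correlated, effects are weak and heterogeneous, and the
negative class is not exchangeable with the positive one.

## Known limitations

- The published benchmark accuracies (76.0% proline / 82.1% lysine) depend
  on a specific Swiss-Prot release and on PSI-BLAST profiles against
  UniRef100; they cannot be recomputed from scratch here. The package pins
  instead the metric identities those numbers imply, the coding-scheme
  constants, and the synthetic recovery gates.
- Plug-in MI on 3-state discretizations is biased upward at small n; this
  matches the cited mRMR practice but is not a calibrated estimator.
- The mRMR implementation is exact greedy, quadratic in the list length ×
  feature count; it is not built for feature spaces beyond ~10⁵.
- 1-NN with jackknife memorizes duplicated windows; identical peptides in
  both classes (possible in real data) are classified by tie-break, and
  near-duplicate proteins inflate jackknife estimates.
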