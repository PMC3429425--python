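# Methods

## Problem and model

`ppisite` predicts, per residue, whether a chain position belongs to a
protein–protein interface. The unit of prediction is a peptide window
of 2w+1 sites (default w = 10, a 21-mer) centered on the candidate
residue; windows centered on annotated interface residues form the
positive class. Positions within w of a chain end are padded with the
letter `X`, and all features of padded sites are set to 0, so every
window encodes to the same fixed-length vector. Chains shorter than 50
residues are dropped before windowing, and windows whose center residue
is predicted buried are removed in both classes — buried residues are
assumed unable to participate in an interface. Sequence-identity
deduplication is an external preprocessing step: the pipeline assumes
its input chains and windows are already non-redundant, and offers
`--max-neg-per-chain` for seeded negative subsampling instead.

### Feature encoding

Per window site, in fixed order: 20 PSSM conservation scores (PSI-BLAST
log-odds, header order A R N D C Q E G H I L K M F P S T W Y V, used
raw), the 5 Atchley amino-acid factors (polarity, secondary-structure
propensity, molecular volume, codon diversity, electrostatic charge;
the published five-factor solution is embedded as a constant, `X` maps
to zeros), 1 disorder score in [0, 1], the 3-state secondary-structure
one-hot (helix = 100, strand = 010, other = 001), and, when 3D
descriptors are available, CX, DPX, AS, MS and SC. That is 34 columns
per site (714 for a 21-mer) or 29 (609) without the 3D group. Columns
are site-major and named `<category>.<subname>@site<k>`, making ranked
feature indices reproducible across runs. Two deliberate choices:

* solvent accessibility is consumed only by the buried-center filter
  and never encoded — it is not part of the 34-column block;
* no feature scaling is applied by default: the random forest is
  scale-invariant and the mutual-information discretization is
  per-feature standardized, so scaling would only obscure provenance
  of the raw annotation values.

### mRMR ranking

Relevance and redundancy are plug-in mutual information in bits.
Continuous features are discretized into 3 states at the feature's own
mean ± one (population) standard deviation: below μ−σ → −1, in
[μ−σ, μ+σ) → 0, at or above μ+σ → +1; a constant column codes to a
one-letter alphabet. This boundary rule maps any binary 0/1 column to a
two-state partition identical to the original column, so one-hot
columns pass through unchanged. Class labels are used as a 2-state
vector directly.

MaxRel sorts features by decreasing D(f) = I(f; c), ties broken by
ascending column index. mRMR selects greedily: round 1 takes argmax D;
round t takes argmax over the not-yet-selected features of D − R (the
difference form, the canonical default; a quotient form D/R is
available behind `--variant quotient`), with R the mean MI between the
candidate and the already-selected features. Zero-variance columns
(e.g. all-zero padded-site columns in small synthetic sets) carry no
information; they are appended after all informative features, in
column order, for determinism. The incremental implementation caches
pairwise MI via a one-hot contingency product; a test asserts its
ordering equals a from-scratch exhaustive greedy recomputation, so the
optimization can never silently change results.

### Incremental feature selection

IFS evaluates the nested prefixes of the ranking with step l (default
1): sizes l, 2l, …, truncated to end at N, i.e. ⌈N/l⌉ subsets, so every
feature is evaluated at least once. Each subset is scored by one
stratified 10-fold cross-validation; the fold partition is drawn once
from the CV seed and shared across all subset sizes, which removes
partition noise from the IFS curve. The optimal subset maximizes MCC,
ties broken toward the smaller subset (parsimony).

### Classifier and metrics

The random forest is scikit-learn's, pinned behind `RFConfig`
(n_trees = 100, unlimited depth, seed = 1 by default; all recorded in
output headers). A sample's score is the fraction of trees voting for
the positive class; the decision threshold k (default 0.5, a sample is
called positive when score ≥ k) produces the confusion matrix for
Sn = TP/(TP+FN), Pr = TP/(TP+FP), Sp = TN/(TN+FP), Ac, and
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)). A zero MCC
denominator yields 0; a zero denominator in a ratio metric yields 0
with a warning. Precision–recall curves enumerate every distinct score
as a threshold and compute each point from the corresponding confusion
matrix.

## Synthetic data

The generator serves two purposes.

`generate_chain_with_tracks` emulates an annotated chain: uniform
random sequence over the 20 amino acids, integer conservation scores in
[−8, 12], uniform disorder, categorical secondary structure
(helix/strand/other at 0.35/0.25/0.40) and accessibility
(buried/exposed at 0.45/0.55), and Gaussian surface descriptors.
Interaction sites are drawn per exposed residue at the positive-site
rate (default 0.35, mirroring the roughly one-in-three positive window
fraction of interface-annotated chains before buried-residue removal),
so the buried filter never removes a positive. These tracks are
statistically self-consistent but stylized: conservation scores are not
alignment-derived, and no track correlates with the interaction labels,
so end-to-end runs on this data test plumbing and layout, not
predictive power on real proteins.

`generate_feature_matrix` emulates the labeled benchmark matrix
directly, with the exact 714-column layout (or 609, or 34 × sites for
other window widths): Gaussian columns with unit noise variance,
within-(site, category)-block correlation ρ produced by one shared
latent factor per block with loading √ρ (pairwise correlation exactly
ρ), and n_informative planted columns whose class-conditional means
differ by effect_size standard deviations. Planted columns are drawn
among the continuous columns; secondary-structure blocks are valid
one-hot draws and carry no planted signal. Defaults (n = 1000 samples,
balanced classes, 5 informative columns, effect size 3, ρ = 0.3,
seed 1) are the conditions used for the recovery checks. Everything is
reproducible from the single spec seed.

## Numerical and degenerate-input choices

* MI is computed from empirical joint counts in base 2; tiny negative
  rounding residues are clamped to 0.
* All tie-breaks (equal relevance, equal mRMR objective, equal IFS MCC)
  resolve toward the lower column index / smaller subset, making every
  ranking and selection deterministic.
* `discretize` rejects NaN/Inf; the encoder rejects windows whose 3D
  features are requested but absent; track readers key rows by 1-based
  position and reject length or range violations naming the track.
* Byte-identical reproducibility: all randomness flows from explicit
  seeds (generator seed, CV seed, forest seed), and output headers
  contain only version, config hash and seeds — no timestamps.

## Desk-scale test conditions

The test suite and verification scripts run the statistical checks at
sizes chosen to keep a full run on one CPU within minutes: mRMR oracle
equivalence on 100 random instances of ≤ 8 features × ≤ 200 samples;
IFS enumeration on a 40-feature, 400-sample matrix; parameter recovery
at the generator defaults (714 columns, n = 1000, effect 3, 10 seeds)
with IFS evaluated over the top-20 ranked prefix with 50-tree forests
(the planted columns rank inside the prefix, so the optimum is
unaffected); null calibration at 714 columns, n = 600, same prefix
scheme, 10 seeds.

## Known limitations

* **Selection optimism.** The pipeline, like the procedure it
  implements, ranks features on the full dataset and then
  cross-validates the nested subsets on that same data. The reported
  IFS metrics are therefore optimistically biased: the ranking has
  already seen every test fold. Under a pure-noise null (effect size 0)
  this bias is large, not negligible — the IFS-maximal MCC has a median
  around +0.2 at the desk scales above, and the magnitude grows with
  the number of candidate features and shrinks only as roughly
  √(log N / n). The cross-validation engine itself is unbiased (a
  data-independent null feature subset scores median MCC ≈ 0.004); the
  optimism is a property of rank-then-validate. Unbiased generalization
  estimates would need a nested CV layer, which is deliberately out of
  scope; users comparing feature sets should treat IFS-table metrics as
  model-selection scores, not generalization estimates.
* The synthetic generator does not emulate realistic PSSM distributions
  or sequence–structure dependence; passing recovery tests demonstrate
  correctness of the selection machinery, not expected performance on
  real interface data.
* The predictor consumes annotation-tool outputs (or synthetic
  stand-ins); it does not run PSI-BLAST, disorder, secondary-structure
  or surface-geometry predictors itself, and does not parse PDB/mmCIF.
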