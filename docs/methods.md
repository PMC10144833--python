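# Methods

## Problem setting and model

`csfpred` treats detection of cerebrospinal-fluid (CSF) proteins as
positive-unlabeled (PU) binary classification: a positive pool P of proteins
experimentally verified in CSF and an unlabeled pool U mixing true negatives
with not-yet-verified secreted proteins. The classifier is a bagging ensemble
built to exploit exactly this structure:

* U is shuffled (seeded) and partitioned into T disjoint subsets of size
  ⌊|U|/T⌋; the remainder (|U| mod T ids) is excluded from training but still
  receives predictions as unseen proteins.
* For each subset, an equal-size sample of P is drawn without replacement
  (independently across the T draws), so every training set is exactly
  class-balanced; unlabeled examples carry label 0, positives label 1.
* Each member is a feed-forward network: hidden layers
  h<sup>l+1</sup> = max(0, W<sup>l+1</sup> h<sup>l</sup> + b<sup>l+1</sup>),
  inverted dropout on each hidden layer, a 2-unit linear output o, and
  p = exp(o₂) / (exp(o₁) + exp(o₂)) as the positive-class probability
  (computed with max-subtraction). Training minimizes mean binary
  cross-entropy with mini-batch Adam; no early stopping, weight decay or
  schedule — a fixed epoch budget.
* Prediction is out-of-bag: the probability of a protein is the mean over
  the members whose training sets exclude it. An unlabeled training protein
  lies in exactly one subset, so it is scored by exactly T−1 members; unseen
  proteins average all T. A protein is called CSF iff p > 0.5, strictly —
  p = 0.5 is negative.

The rationale for bagging over disjoint unlabeled subsets is that hidden
positives contaminate each member's "negative" examples only locally; the
out-of-bag average removes the optimistic bias a model has toward samples it
trained on.

### Default hyperparameters

| parameter | default | notes |
|---|---|---|
| T (members) | 16 | partition count of U |
| hidden layers | 128, 128, 128 | ReLU |
| dropout | 0.1 | hidden layers, training only |
| batch size | 32 | |
| Adam learning rate | 0.001 | β₁ 0.9, β₂ 0.999, ε 1e-8 |
| epochs | 20 | fixed |
| decision threshold | 0.5 | strict inequality |

Per-member seeds are spawned deterministically from the master seed via
`SeedSequence([seed, t])`; weight initialization is He-normal, biases zero.

## Featurization

52 named feature blocks, 1610 dimensions, in four groups (general 11 blocks /
1085 dims; physicochemical 24 / 484; domain–motif 11 / 15; structural 6 / 26).
The shipped YAML (`csfpred/data/default_blocks.yaml`) is the source of truth;
any block subset or re-parameterization can be supplied instead.

Key construction choices (the cited literature behind this family of
descriptors fixes the formulas; the layout parameters are configuration):

* Autocorrelation (normalized Moreau–Broto, Moran, Geary): 3 z-scored scales
  (Kyte–Doolittle hydrophobicity, Grantham polarity, Charton polarizability)
  × 30 lags = 90 dims each. A property constant along the sequence gives 0
  for Moran/Geary (zero-variance convention); lags ≥ sequence length are
  flagged missing.
* Quasi-sequence-order: per residue-distance matrix, 20 composition terms
  plus 60 squared-distance coupling terms sharing the denominator
  1 + w·Στ, w = 0.1; two matrices × 80 = 160 dims. The first matrix is
  Grantham's chemical distance recomputed from his composition/polarity/
  volume properties (mean-100 scaling; Leu–Ile ≈ 5 reproduces the published
  table). The second is a Schneider–Wrede-style stand-in: Euclidean distance
  over z-scored hydrophobicity, hydrophilicity and side-chain mass,
  max-normalized — the published matrix itself is not reproducible from
  accessible sources, and the diagonal-zero property the descriptors rely on
  is preserved.
* Pseudo-amino-acid composition: type-1 with λ = 130, weight 0.05, over the
  classic hydrophobicity / hydrophilicity / side-chain-mass trio (z-scored);
  length 150. Amphiphilic variant: λ = 30, interleaved hydrophobicity and
  hydrophilicity correlation terms, length 80. Both share the common
  denominator, so computed blocks sum to 1. Sequences of length ≤ λ get a
  missing-flagged block rather than an error — by construction the synthetic
  generator produces such sequences, and real proteomes contain them.
* Physicochemical profiles (21 dims per scale): entries 1–20 are the residue
  composition weighted by the raw scale value per residue type, entry 21 the
  sequence mean of the scale. Scales with canonical 20-value tables use the
  literature values (several via Biopython); the remaining named scales
  (surface tension, water solubility, CLogP and the interface/binding
  propensity family) are deterministic synthetic stand-ins in
  `synthetic_scales.py`, clearly labelled — users with the real tables can
  substitute them, or supply the profiles via the external-feature path.
* Mass uses average residue masses plus one water (via Biopython);
  the isoelectric point is solved by bisection on the Henderson–Hasselbalch
  net charge. "Total amino-acid property" is the sequence sum of raw
  hydrophobicity, charge and polarity.
* Domain/motif (15 dims) and structural (26 dims) blocks come from external
  predictors (signal peptide, transmembrane, glycosylation, phosphorylation,
  disorder, secondary structure, …). They are never recomputed internally —
  re-implementing those predictors is out of scope — and default to missing,
  to be filled by `ingest_external_features` from a TSV keyed by protein id.

Non-standard residue letters (B/J/O/U/X/Z) are stripped with a warning by
default (policy `reject` available): property values for them are undefined,
and stripping keeps real FASTA usable.

## Preprocessing

Missing values are imputed with per-column training medians, then columns are
standardized by the training mean and population (divide-by-n) standard
deviation. Zero-variance columns map to 0, keeping downstream rank tests
well-defined. Statistics are always learned on the training partition only;
the library API makes leakage structurally impossible (fit returns a state
object; transform never re-estimates).

## Feature selection

Stage one: per-dimension two-sided Wilcoxon rank-sum test (normal
approximation with tie and continuity corrections; a constant column gets
p = 1), Benjamini–Hochberg step-up q-values, retain iff q ≤ α (default 0.05).
Stage two: recursive feature elimination using the stage-one q-values as a
fixed importance ranking — each iteration drops the `step` = 20 surviving
columns with the largest q (ties broken stably by column order), retrains a
surrogate classifier on the training split and records validation F1 and
AUC; the final partial iteration drops down to a floor of one column. The
selected subset is the smallest feature count scoring within ε = 0.005 of
the curve maximum (criterion AUC by default). Because BH preserves the
p-value ordering, ranking by q or by p gives the identical elimination
order. The surrogate is a single network with the ensemble architecture and
a fixed seed per fit, so the curve is reproducible; using the full T-model
ensemble as the RFE base model would cost T× more for the same ordering.

## Differential expression and biomarker intersection

Expression matrices (FPKM-like, genes × samples) are transformed with
log2(x+1) and quantile-normalized across samples (each sample's sorted
values replaced by cross-sample means of sorted values; ties get midrank
interpolation). Quantile normalization is the deterministic choice for the
normalization contract; an identity normalizer is available and the step is
pluggable. Per-gene significance is the same rank-sum + BH machinery (a
single implementation shared with feature selection). Fold change
FC = Σ(case)/Σ(control) is computed on the raw scale — ratios of raw sums,
not of log values; rank-sum p-values are invariant under the monotone log
transform, so only FC is scale-sensitive. Calls: up iff q ≤ 0.05 and
FC > 2, down iff q ≤ 0.05 and FC < 0.5. Degenerate FC: +inf when only the
control sum is 0, 1 when both sums are 0 (flagged).

Gene calls propagate to proteins through a two-column mapping (many-to-many
allowed); a protein inheriting conflicting directions is excluded as
ambiguous rather than arbitrated. Differentially expressed proteins are then
partitioned into verified CSF proteins (membership in the verified list
overrides any prediction), predicted candidates (probability > 0.5, not
verified) — the biomarker candidates — and the rest.

## Synthetic data: what it emulates and what it does not

* `gen_pu_sequences`: two residue-composition distributions obtained by
  tilting proteome-average frequencies by exp(±shift/2) along a fixed ±1
  direction; per-protein composition drawn from a Dirichlet (concentration
  200) around the class mean; lengths uniform on 50–300 so that λ- and
  lag-infeasible blocks genuinely occur. A fraction (default 0.2) of the
  unlabeled pool are hidden positives drawn from the positive distribution,
  with the latent truth recorded. Defaults: 300 positives, 600 unlabeled.
* `gen_feature_table`: Gaussian columns, informative ones mean-shifted by
  the effect size in the positive class.
* `gen_expression`: per-gene log-normal baseline, log-normal sample noise
  (sd 0.5 on the natural-log scale), planted genes multiplied by the effect
  fold change (default 4×/0.25×, 50 + 50 of 1000 genes, 40 + 40 samples).

These generators reproduce the *statistical* structure the method assumes —
class-dependent composition, PU contamination, planted fold changes — but
not the biology of real secretomes: no domains, homology, signal peptides or
length/abundance correlations. Passing tests therefore validate the
machinery and its operating characteristics under known truth, not
real-data performance; the external-predictor feature blocks are absent
(median-imputed) throughout the synthetic studies.

## Numerical conventions

* Probabilities are clipped to [1e-7, 1−1e-7] inside the loss; softmax uses
  max-subtraction.
* Zero-denominator evaluation scores (PR, F1, MCC, …) are defined as 0 with
  a warning; AUC uses midranks for ties.
* BH q-values, medians and rank statistics delegate to
  statsmodels/numpy/scipy; every such primitive is cross-checked in the test
  suite against an independent brute-force implementation.
* All randomness flows from explicit integer seeds; identical configuration
  and seed give bit-identical featurization and matching predictions.

## Problem sizes used in the shipped studies

The test suite and `scripts/acceptance.py` run the ensemble pipeline at
300 + 600 training sequences and a same-size held-out draw (the held-out set
is full-size so the Monte-Carlo error of a null AUC estimate is ≈ 0.02),
with T = 8 members; selection studies use 500 + 500 samples over 500
columns; expression studies 1000 genes × 80 samples. These sizes were chosen
so each study estimates its quantity with comfortable Monte-Carlo margins
while the whole battery runs in well under a minute.

## Known limitations

* The domain/motif and structural feature groups are ingestion-only; the
  package cannot populate them without external predictor output.
* Thirteen physicochemical profile scales and the second quasi-sequence-order
  distance matrix are synthetic stand-ins (see above); block layouts and all
  downstream machinery are unaffected, but absolute values of those
  dimensions are not literature values.
* The rank-sum test uses the normal approximation; for very small groups
  (< ~8 per class) an exact test would be preferable.
* Quantile normalization is one defensible choice for the normalization
  contract; results for borderline genes can differ under other schemes.
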