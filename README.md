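# csfpred

Prediction of proteins secreted into cerebrospinal fluid (CSF), and its
application to screening biomarker candidates for central-nervous-system
disease from differential gene expression.

Experimentally cataloguing the CSF proteome is slow and expensive, so the
label structure of the problem is positive-unlabeled (PU): a set of proteins
verified in CSF by wet experiments, and a large pool of proteins that are
simply unverified — some of which are secreted but not yet observed.
`csfpred` implements a complete pipeline for this setting:

1. **Sequence featurization** — each protein sequence is encoded as a named
   1610-dimension vector over 52 feature blocks in four groups: general
   sequence descriptors (amino-acid composition, dipeptide composition,
   normalized Moreau–Broto / Moran / Geary autocorrelation, quasi-sequence-
   order, pseudo- and amphiphilic pseudo-amino-acid composition, length,
   mass, summed properties), physicochemical property profiles (21 dims per
   scale plus the isoelectric point), and domain/motif and structural blocks
   (signal peptide, transmembrane, glycosylation, disorder, secondary
   structure, …) ingested from external predictors rather than recomputed.
   Infeasible blocks (e.g. a sequence shorter than a correlation lag) are
   flagged missing, then median-imputed and standardized with statistics
   learned on training data only.
2. **Two-stage feature selection** — per dimension, a two-sided Wilcoxon
   rank-sum test against the CSF label with Benjamini–Hochberg q-values
   removes irrelevant dimensions (retain iff q ≤ 0.05); recursive feature
   elimination ranked by those q-values (drop the 20 worst per iteration,
   retrain, score F1/AUC on validation data) removes redundant ones, keeping
   the smallest subset within ε of the best validation score.
3. **PU bagging ensemble** — the unlabeled pool U is partitioned into T
   disjoint equal-size subsets, each paired with an equal-size random sample
   of the positives P, giving T exactly class-balanced training sets. T
   feed-forward networks h<sup>l+1</sup> = max(0, W h<sup>l</sup> + b) with
   three 128-unit hidden layers, dropout 0.1 and a 2-unit softmax output are
   trained with Adam (lr 0.001, batch 32, 20 epochs) on mean cross-entropy.
   A protein's score is the **out-of-bag** average
   p = mean over { models whose training set excludes it } of
   softmax₂(o), and it is called a CSF protein iff p > 0.5 (strict).
4. **Biomarker screening** — case/control expression matrices are
   log2(x+1)-transformed and quantile-normalized; genes with q ≤ 0.05 and
   fold change FC = Σc/Σn > 2 (or < 0.5) are called up-/down-regulated,
   mapped to proteins, and intersected with the predictions: differentially
   expressed proteins that are predicted secreted but not yet experimentally
   verified are the candidate biomarkers.

A seed-reproducible synthetic-data module generates PU sequence sets with
hidden positives, tabular feature sets with planted effects, and expression
matrices with planted fold changes, so the whole pipeline is testable without
any external database.

## Worked example

```python
import numpy as np
from csfpred.synthetic_data import SequenceGenConfig, gen_pu_sequences
from csfpred.sequence_features import build_feature_matrix
from csfpred import preprocessing, pu_ensemble as pe, metrics

train = SequenceGenConfig(n_pos=300, n_unlabeled=600, composition_shift=0.5, seed=1)
records, pos, unl, _ = gen_pu_sequences(train)
fm = build_feature_matrix(records)
print(f"feature matrix: {len(fm.protein_ids)} proteins x {len(fm.column_names)} dimensions")

state = preprocessing.fit_scaler(fm)
z = preprocessing.transform(fm, state)
row = {p: i for i, p in enumerate(z.protein_ids)}
ens = pe.train(pos, z.values[[row[p] for p in pos]],
               unl, z.values[[row[p] for p in unl]],
               pe.EnsembleConfig(input_dim=z.values.shape[1], T=8, seed=1))

held = SequenceGenConfig(n_pos=300, n_unlabeled=600, composition_shift=0.5,
                         seed=2, id_prefix="EV")
erecs, epos, eunl, etruth = gen_pu_sequences(held)
ez = preprocessing.transform(build_feature_matrix(erecs), state)
p = ens.predict_many(ez.protein_ids, ez.values)
y = np.array([1] * len(epos) + [1 if etruth[u] else 0 for u in eunl])
print(f"held-out AUC = {metrics.auc(y, p):.4f}")
s = metrics.scores(metrics.confusion(y, pe.classify(p)))
print(f"ACC = {s['ACC']:.4f}, F1 = {s['F1']:.4f}, MCC = {s['MCC']:.4f}")
```

prints

```
feature matrix: 900 proteins x 1610 dimensions
held-out AUC = 0.9988
ACC = 0.9822, F1 = 0.9808, MCC = 0.9644
```

i.e. with a composition shift of 0.5 between the classes, the out-of-bag
ensemble recovers the hidden labels of a same-size held-out draw — including
the 20% hidden positives inside its unlabeled pool — almost perfectly. The
41 externally-sourced feature dimensions are absent for synthetic sequences
and are median-imputed (a warning notes this).

The same pipeline is available from the shell:

```
csfpred --seed 1 simulate pu --out-dir sim
csfpred featurize --fasta sim/sequences.fasta --out features.tsv
csfpred --seed 1 select --features features.tsv --positives sim/positives.txt --out-dir sel
csfpred --seed 1 train --features features.tsv --positives sim/positives.txt \
        --unlabeled sim/unlabeled.txt --columns sel/selected_columns.txt --out model
csfpred predict --model model --features features.tsv --out pred.tsv
csfpred evaluate --truth sim/positives.txt --pred pred.tsv --out metrics.json
```

plus `de`, `biomarkers` and `simulate expression` for the differential-
expression stage.

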