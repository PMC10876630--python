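# ddiconv

Multimodal convolutional prediction of **drug–drug interaction (DDI) events**.

When two drugs are co-administered, their interaction produces one of many
categorized pharmacological events (altered serum concentration, potentiated
QTc prolongation, reduced metabolism, ...).  `ddiconv` predicts *which* event
class a drug pair produces — a multi-class problem over known interacting
pairs, not binary interaction detection — from four drug-feature modalities:
chemical substructure keys, targets, enzymes, and pathways.  It is aimed at
computational pharmacology researchers who want a self-contained, fully
testable implementation of the similarity-profile + fused-CNN approach to
DDI event prediction, including its ablation, baseline, and significance
machinery.

## Method

1. **Encoding.** Each drug *d* is described per modality by a finite token
   set; tokens are encoded as a binary fingerprint *x_d ∈ {0,1}^V* over the
   modality vocabulary (e.g. 808 substructure keys / 1162 targets /
   202 enzymes / 957 pathways in the public 572-drug benchmark).
2. **Similarity profiles.** Fingerprint sparsity is compressed into an
   N × N drug–drug similarity matrix per modality with the Jaccard index

       J(d, e) = |x_d ∩ x_e| / |x_d ∪ x_e|  ∈ [0, 1]

   (cosine similarity is available as an alternative).  A pair (a, b) is
   represented, per modality, by the concatenation of the two drugs'
   similarity rows (length 2N).
3. **Fused convolutional classifier.** One sub-model per modality: a 1-D
   convolution (1 filter, kernel 5, `tanh`), flatten, then dense blocks of
   1024 → 512 → 256 units, each affine → batch-norm → `elu` → dropout 0.3.
   The four 256-wide representations are concatenated and mapped by a single
   affine layer to an E-way softmax over event classes (E = 65 for the
   public benchmark; read from data).  Training uses Adam on categorical
   cross-entropy.  The network, including backpropagation, is implemented in
   NumPy (`ddiconv.nn`).
4. **Evaluation.** Accuracy, macro/micro F1, micro-averaged ROC-AUC and
   AUPR over the flattened instance × class matrices, precision@k ranking,
   stratified k-fold CV, feature-set ablation over all 15 non-empty modality
   subsets, a (layers × activation) hyperparameter grid, and comparison
   against random forest (100 trees), KNN (k = 4), logistic regression and a
   dense-only network on shared folds with paired t-tests and one-way ANOVA
   at α = 0.05.

Because the public DrugBank-derived dataset cannot be redistributed, the
package ships a **synthetic benchmark generator** (`ddiconv.synth`) that
plants a learnable event rule: drugs belong to families, modalities carry
family archetype token sets, and a pair's true event is the argmax of
per-class prototype scores on the pair's combined token counts, with
configurable label noise.  The generator returns an oracle labeler whose
agreement with the observed labels is the ceiling any model can reach.

## Worked example

```bash
ddiconv synth --scale small --out data/           # 120 drugs, 8 events, 900 pairs
ddiconv encode --features data/drug_features.tsv --out enc/
ddiconv compare --features data/drug_features.tsv \
                --interactions data/interactions.tsv \
                --out results/ --epochs 12 --batch-size 128 --folds 5
```

`encode` prints the modality vocabularies and matrix shapes (at this scale
the observed vocabulary is the union of the drug families' archetype token
sets, so it is smaller than the configured universe):

```
enzyme: vocabulary size 18, matrix 120x120
pathway: vocabulary size 70, matrix 120x120
substructure: vocabulary size 57, matrix 120x120
target: vocabulary size 91, matrix 120x120
```

`compare` (seed 0) prints the model-vs-baseline table (per-fold means) and
the significance report:

```
             Method      ACC       F1      AUC     AUPR
         fused_conv 0.848889 0.838507 0.941348 0.819214
      random_forest 0.850000 0.842808 0.942038 0.823684
                knn 0.833333 0.822682 0.929008 0.775693
logistic_regression 0.840000 0.825280 0.939755 0.828628
```

followed by a per-metric significance table (also written to
`significance.tsv`) holding the paired t statistic, p-value, and α = 0.05
flag for the fused model against each baseline plus the one-way ANOVA
across all models — here the fused model beats KNN on AUPR (t = 4.90,
p = 0.008) and is statistically indistinguishable from the rest.  That is
expected on this small noisy benchmark: 10% of labels are deliberately
flipped, so the oracle ceiling is ≈ 0.90 and all strong learners crowd it;
clearer separation appears at the medium scale (400 drugs), where
`scripts/acceptance.py` measures it.

`ddiconv ablate` emits the 15-row feature-subset table (S, T, E, P and all
combinations) and `ddiconv grid` the layers × activation grid, both as TSV
mirroring the ACC/F1/AUC/AUPR column convention.

## Reproducing at full scale (external data required)

With the public DDIMDL-format distribution (572 drugs; delimited tables of
drug features and pairwise interaction events derived from DrugBank,
https://go.drugbank.com/), convert the feature table to the long
`drug_id, modality, token` format and interactions to
`drug_a, drug_b, event`; `ddiconv.dataset.load_interactions_sqlite` adapts
the SQLite ("event.db") distribution.  Expected checkpoints: vocabulary
sizes 808/1162/202/957, four 572 × 572 similarity matrices, 74,528 raw →
37,264 unique pairs, and 5-fold CV accuracy approaching ≈ 0.90 after full
training (~100 epochs).  This path needs the external download and several
CPU-hours; it is not exercised by the test suite.
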