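# Methods

## Problem and model

`ddiconv` treats drug–drug interaction (DDI) event prediction as multi-class
classification over known interacting pairs.  The model family is a fused
multi-input convolutional network over per-modality drug–drug similarity
profiles:

- **Input.** For each modality m (substructure, target, enzyme, pathway) a
  pair (a, b) is the concatenation of the two drugs' rows of the N × N
  Jaccard similarity matrix, a vector of length 2N.  Concatenation (rather
  than sum or difference) preserves per-drug information and gives the
  convolution a well-defined input length; appending the mirrored (b, a)
  orientation is available as a training-augmentation flag, off by default.
- **Sub-model.** 1-D valid convolution, stride 1, 1 filter of kernel width 5
  with `tanh`; flatten; dense blocks 1024 → 512 → 256, each ordered
  affine → batch normalization → `elu` → dropout 0.3.  The block ordering
  and the (1 filter, kernel 5) reading of the architecture are configurable
  (`SubmodelSpec`), as are filter count, activations and widths.
- **Fusion.** Default `concat`: the per-modality 256-vectors are
  concatenated and a single affine layer + softmax maps to the E event
  classes.  Alternative `average`: one softmax head per branch, predictions
  are the arithmetic mean of head probabilities (the predecessor-style
  design, kept for ablation).
- **Training.** Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-7) on categorical
  cross-entropy.  Defaults: batch 256, 100 epochs, learning rate 1e-3,
  optional per-epoch multiplicative learning-rate decay (`lr_decay`,
  default 1.0 = off), early stopping with patience 10 on a 10% validation
  split with best-weight restore.  All randomness (initialization, batch
  shuffling, dropout) flows from one root seed via `numpy` `SeedSequence`
  spawning; inference is deterministic.

The network is implemented directly in NumPy (`ddiconv.nn`: conv, dense,
batch-norm, inverted dropout, softmax cross-entropy, Adam) with hand-written
backward passes, verified in the test suite by central-difference gradient
checks.  Arithmetic is float32; losses and probabilities are accumulated in
float64.

### Numerical conventions

- Jaccard for two all-zero fingerprints is defined as 0 (0/0 is undefined;
  no shared evidence means no similarity), so similarity entries always lie
  in [0, 1] with unit diagonal for non-empty drugs.  For binary vectors the
  Jaccard index cannot be negative; the input `tanh` nonlinearity is kept
  for architectural fidelity, not because of the input range.
- Vocabulary order is lexicographic, making encodings reproducible.
- Ranking ties in precision@k break by record index; micro AUC follows the
  Mann–Whitney tie convention (half credit), micro AUPR is the step-integral
  average-precision form.
- Deduplication of interaction records keeps the first occurrence of each
  unordered pair and logs label conflicts.
- Degenerate statistics follow fixed contracts: zero-variance zero-mean
  paired differences → (t, p) = (0, 1); zero-variance nonzero differences →
  (±inf, 0) with a warning; all-identical ANOVA groups → (F, p) = (0, 1)
  with a warning.
- Stratified k-fold assigns classes with fewer than k members round-robin
  across folds (warned), preserving per-class proportions within ±1
  elsewhere.
- F1 is macro-averaged by default and micro as an option (the averaging
  used by comparable reports is unstated, so both are exposed); AUC/AUPR are
  micro-averaged over the flattened instance × class matrices.

## Synthetic benchmark

The generator (`ddiconv.synth`) exists so every stage — encoding, training,
ablation, statistics — is testable without the restricted DrugBank-derived
dataset.  It emulates the structural features that make the real task
learnable while staying fully controlled:

- **Drug families.** Drugs are assigned to equal-size families (20 at the
  medium scale, i.e. 20 drugs per family).  Each modality has one archetype
  token set per family (tokens drawn i.i.d. with the configured presence
  probability, ~5%); a drug's token set is the archetype of its *modality
  view*.  Informative modalities view the drug's family with a small outlier
  rate (`view_noise`, 3%) emulating modality-specific annotation errors; the
  non-informative modality receives an independent equal-size grouping, so
  it carries no information about the label — and, because drugs in one
  group share identical similarity rows, it cannot leak drug identity
  either.  Annotation sharing within families mirrors real data, where drugs
  of one class list the same targets, enzymes and pathways; what it does
  *not* emulate is per-drug fingerprint individuality or realistic marginal
  token frequencies, so passing tests show that the pipeline recovers
  family-structured signal, not that it would reach any particular accuracy
  on DrugBank data.
- **Planted event rule.** One prototype weight vector per event class over
  the informative vocabularies; a pair's true event is the argmax of
  prototype scores on the pair's combined token counts.  The prototypes are
  constructed by a least-norm solve against the archetype matrix so that
  each family has a *preferred class* (assigned round-robin; strength 4)
  with unit-variance Gaussian cross-terms deciding which drug's preferred
  class wins a given pair.  This keeps the event histogram near uniform
  (max/min count ratio < 3 at the medium scale) while the label remains a
  genuine linear-prototype argmax — learnable by the network and by the flat
  baselines alike, which is what makes comparative experiments meaningful.
- **Label noise.** Observed labels flip to a uniformly random *other* class
  with probability `noise` (10% at the small/medium scales), modelling
  annotation ambiguity.  The returned oracle labeler reproduces the
  noise-free rule, so its agreement with observed labels (~0.90) is the
  ceiling against which models are judged.

Scales: `tiny` (20 drugs / 3 events / 100 pairs, noise-free; unit tests),
`small` (120 drugs / 8 events / 900 pairs; integration), `medium` (400
drugs / 20 events / 8000 pairs ≈ 10% pair density vs ~23% in the public
benchmark; desk-scale experiments).

## Desk-scale training protocol

The full-scale default protocol (100 epochs, batch 256) is unnecessary and
wasteful at benchmark scale; desk-scale experiments and
`scripts/acceptance.py` use 12 epochs, batch 128, learning rate 1e-3 with a
0.85 per-epoch decay, early stopping off.  Under this protocol on the medium
benchmark the fused model reaches ~0.86 five-fold CV accuracy against an
oracle ceiling of ~0.90; single informative modalities land around
0.72–0.79, and the non-informative enzyme branch at chance (~0.05–0.13
depending on seed).  These numbers are recomputed, not asserted, by the
acceptance script and the test suite.

## Design choices made where the design was open

- **Pair representation** (concatenated similarity rows) and **pair-level
  CV splits**: cold-start drug-level evaluation is out of scope.
- **Fusion** defaults to concat-then-softmax, the reading best supported by
  a single fused output layer; per-branch heads with averaged predictions
  are retained as an option.
- **Baseline inputs**: all modalities' pair vectors concatenated into one
  flat vector — the only representation a flat classifier can consume — with
  the same folds as the fused model.  RF = 100 trees, KNN k = 4, logistic
  regression with library defaults (recorded in report metadata); the
  dense-only ablation is the fused model with its conv front switched off.
- **Grid semantics**: the "layers" axis counts dense blocks, using the
  halving ladder 1024/512/256/128 truncated to the requested depth.
- **Statistics**: both the paired t-test and one-way ANOVA are applied to
  every metric column across folds, since which metric the comparison should
  use is a reporting choice, at fixed α = 0.05.

## Known limitations

- The synthetic benchmark's family structure is deliberately strong;
  real fingerprints have graded within-class similarity, so real-data
  accuracy is not predicted by these experiments.
- Similarity profiles include each drug's self-similarity, so with
  pair-level splits any modality that individuates drugs can be partially
  memorized; on real data even a label-irrelevant modality will sit above
  chance for this reason.
- The NumPy engine targets clarity and desk scale; it is single-threaded
  BLAS-bound and has no GPU path.
- Event labels arrive as dense integers; extracting event categories from
  free-text interaction descriptions is out of scope.
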