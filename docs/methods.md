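# Methods

## Problem and model

`dtitransfer` treats drug–target interaction (DTI) prediction as ligand-based
binary classification at the protein-family level: given a fixed-length
numeric representation **x** ∈ ℝ³⁰⁰ of a compound, predict whether it is
active (pChEMBL ≥ 7.0, i.e. XC50 ≤ 100 nM) against a family. The question the
package is built to answer is *how little* target-family data suffices when a
related, data-rich source family is available.

The trainable backbone is a two-hidden-layer feed-forward network (FNN-2):

    x (300) → ReLU(1200) → ReLU(300) → softmax(2)

trained with mini-batch Adam on cross-entropy. Reference hyperparameters:
learning rate 1e-4, 100 epochs, batch size 256. Activation, optimizer and
loss (ReLU / Adam / cross-entropy) are fixed choices exposed through
`FNNConfig`; there is no dropout, weight decay or early stopping by default.
The output head is a 2-logit softmax rather than a single sigmoid unit so
that head replacement in the frozen transfer modes is symmetric.

Training is two-staged. **Stage I** fits the FNN on the source family from a
seeded He-normal initialization. **Stage II** adapts it to a small
target-family training set in one of three modes:

* **Mode 1 — full fine-tuning.** All layers initialized from the source
  model and re-trained. At epoch 0 the target model *is* the source model
  (an exact, bit-level identity the tests enforce).
* **Mode 2 — feature transformer.** Both hidden layers frozen (bit-identical
  before/after, by construction: frozen layers are simply excluded from the
  optimizer); only the output layer is re-trained.
* **Mode 3 — shallow classifier.** The output layer is replaced by an SVM
  (RBF kernel, C = 1, variance-scaled gamma) fit on the frozen 300-d
  second-hidden-layer activations. Source parameters are never touched.

Baselines: the *scratch reference* (the same FNN trained from random
initialization on the target subset only), the *base model* (an SVM on the
raw 300-d input vectors), and the *zero-shot* setting (the unmodified source
model applied to target data).

The FNN is implemented directly in numpy (forward, backward, Adam); at this
architecture size a hand-rolled float32 implementation is fast on one CPU
core and makes the freezing/bit-reproducibility contracts easy to guarantee.
Gradients were validated against central finite differences during
development.

## Data curation

Raw bioactivity tables are reduced to labeled compounds in a fixed order:

1. **Attribute filters** — keep target type `SINGLE PROTEIN`, human targets,
   binding assays (functional assays can be re-admitted via config), and
   XC50-class standard types (IC50, EC50, AC50, Ki, Kd, Potency); drop rows
   without a pChEMBL value.
2. **Median aggregation** — repeated measurements of the same
   (compound, target) pair collapse to their median pChEMBL. The presence
   filter runs first because the median is only defined over numeric values.
3. **Labeling** — active iff pChEMBL ≥ threshold (default 7.0). The boundary
   case (exactly 7.0) is labeled *active*; a config switch flips this to a
   strict inequality.

## Representations and splitting

Two representations serve two different jobs:

* **ECFP4 (Morgan radius-2, 2048 bits)** fingerprints feed Butina leader
  clustering at Tanimoto similarity ≥ 0.8. Whole clusters are assigned to
  train or test (largest clusters to test first, seeded shuffle among
  equal sizes, default test fraction 1/6), so no chemical series straddles
  the evaluation boundary. Tie-breaks in the leader ordering use ascending
  compound id for cross-platform determinism; empty-vs-empty Tanimoto is
  defined as 1.0. Overshoot past the test-fraction target is tolerated
  rather than splitting a cluster.
* **Classifier vectors (300-d)** are either imported learned embeddings
  (any external representation model; a TSV of id + 300 floats) or, as the
  self-contained default, the ECFP4 fingerprint hashed directly to 300
  0/1 bits.

Controlled low-data experiments draw *balanced* subsets (exactly n/2 actives
and n/2 inactives, without replacement) of sizes 2, 6, 12, 48, 96, 400,
1000, 4000 from the training partition. Test sets keep their natural class
ratio. Within a benchmark repeat, every competing model sees the identical
subset draw (paired design), and all are evaluated on the same fixed test
set. MCC is the headline metric (denominator-zero convention: 0); AUROC,
precision, recall, F1 and accuracy are reported alongside (AUROC of a
single-class test set is undefined and reported as 0.5).

## Synthetic families

The transfer machinery only ever sees 300-d vectors, so the generator aims
for statistical rather than chemical realism. Family *f* has a unit decision
direction

    w_f = normalize( √ρ · w₀ + √(1−ρ) · u_f )

with w₀ shared and u_f family-specific; the overlap ρ ∈ [0, 1] controls task
relatedness (⟨w_f, w_g⟩ ≈ ρ). Features are i.i.d. standard normal; the label
is 1{⟨w_f, x⟩ > 0}, flipped with probability ε. A signal parameter can
stretch points along w_f to widen the margin (default 1.0 — no stretching,
so the Bayes accuracy is exactly 1 − ε). Pseudo-fingerprints with planted
cluster structure (random 64-bit centroid patterns, 3-bit member
perturbations) exercise the clustering and splitting machinery: intra-cluster
Tanimoto is ≥ ~0.83 by construction, inter-cluster near zero.

Reference study conditions (used by the acceptance checks and the
`scripts/acceptance.py` report): ρ = 0.8, ε = 0.1, source n = 5000, target
training pool n = 2000, target test n = 1000, 20 paired repeats, training
sizes {2, 6, 12, 48, 96} for all modes plus {1000} for the
fine-tune-vs-scratch gap. These sizes keep the whole study within minutes on
a single CPU core while leaving the per-size comparisons well resolved.

### What the generator does and does not emulate

It reproduces the *regime* of the real problem — a large related source
task, a small target task, controllable relatedness — and that is exactly
what the transfer claims need. It does **not** emulate several features of
real bioactivity data, and results on it should be read accordingly:

* **No family-specific base rates or calibration mismatch.** Every family is
  exactly class-balanced with a boundary through the origin, so a source
  model is already calibrated for the target. In real data, part of the
  benefit of even a two-compound fine-tune is correcting base-rate and
  threshold mismatch between families; that benefit does not exist here. In
  consequence, two-example fine-tuning performs at (marginally below)
  zero-shot level on the synthetic task instead of above it, as paired
  measurement over 20 repeats shows. A per-family intercept would change
  this, and is deliberately not part of the generator's construction.
* **Confidence is unconstrained.** With 10% label noise and no
  regularization, Stage-I training memorizes the source set (training
  cross-entropy ≪ 1, median softmax confidence ≈ 0.99). The source model is
  then confidently wrong on the ~28% of target points it misses, so its mean
  cross-entropy on target subsets is *higher* than that of an uninformed
  fresh initialization even though its accuracy and MCC are far better.
  First-epoch *loss* comparisons between fine-tuning and scratch therefore
  favor scratch on this generator, while every MCC comparison favors
  transfer. This is a calibration artifact of cross-entropy, not a transfer
  failure.
* Features are isotropic; real learned embeddings are strongly anisotropic
  (low intrinsic dimension), which makes tiny-sample adaptation easier than
  it is here.

## Numerical and reproducibility choices

* float32 parameters and activations; loss accumulated in float64.
* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; grid-cell seeds derive from
  (master seed, repeat, size index), so re-running a benchmark with the same
  master seed reproduces every record bit-exactly, and frozen layers are
  bit-identical across training by construction.
* Checkpoints are single-file `.npz` archives of per-layer arrays plus a
  JSON metadata block; save/load round-trips are bit-exact, so Mode-2
  freezing contracts survive serialization.
* Degenerate inputs fail loudly: single-class training sets, all-frozen
  masks, empty datasets, ragged embedding rows, overlapping split manifests
  and infeasible subset sizes all raise typed errors (an infeasible size
  inside a benchmark grid is skipped with a warning instead, so one
  oversized request does not void a run).

## Known limitations

* The representation learner itself (message-passing network) is out of
  scope; imported embeddings are taken as given.
* The SVM hyperparameters are not tuned per dataset (C = 1 throughout).
* Butina clustering is O(n²) in similarity evaluations; it is intended for
  per-family curation scale, not database scale.
* Test sets are not balanced; MCC on strongly imbalanced test sets has
  higher variance at small test sizes.
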