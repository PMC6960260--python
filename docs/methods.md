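# Methods

## Problem and model

Enhancers are distal cis-regulatory DNA elements, and most of them act
tissue-specifically. Discriminating enhancers from non-enhancer DNA
(anywhere in the genome) is well served by deep sequence models, but
*tissue-specific* enhancer prediction is data-starved: a single tissue
typically contributes only a few hundred positive sequences, far fewer
than the parameters of any reasonable network.

`enhprs` implements the pretraining–retraining strategy (PRS) for this
setting:

1. **Pretraining** — train one network, with validation-based epoch
   selection, on the large set of broadly active ("housekeeping")
   enhancers selected from an eRNA activity matrix.
2. **Retraining** — for each tissue, warm-start from the pretrained
   checkpoint and train for a small, fixed number of epochs (default 20)
   on that tissue's small dataset. The ab-initio baseline trains the same
   budget from random initialization.

The classifier is a hybrid convolutional/recurrent network:

    one-hot (L x 4) → Conv(F filters of length m, valid, stride 1) → ReLU
      → non-overlapping MaxPool(p) → Dropout
      → bidirectional GRU over pooled positions → concat final states
      → Dense(32, ReLU) → scalar → sigmoid ŷ ∈ (0, 1)

The convolution filters `M` act as learned motif detectors; the Bi-GRU
models how detected motifs combine along the sequence in either
orientation (enhancers function bidirectionally); the dense layer `WM`
and a scalar projection produce the probability. The pooled length is
`floor((L − m + 1) / p)` and the GRU runs over exactly that many steps.

Training minimizes mean binary cross-entropy plus L1 penalties on the
three named parameter groups, and epoch selection minimizes the
*validation* objective

    objective_va = crossentropy_va + λ1·‖M‖₁ + λ2·‖WU‖₁ + λ3·‖WM‖₁

The returned parameters are the checkpoint of the epoch minimizing this
objective, never simply the last epoch. `WU` denotes the GRU gate weight
matrices (update, reset, candidate memory — input and recurrent
projections for both directions, stored as two stacked matrices per
direction). Biases and the final scalar projection are excluded from all
three penalty groups, the standard convention for norm penalties on
weight matrices.

The network and its backward pass are implemented directly in numpy
(including backpropagation through time for both GRU directions) and
optimized with Adam. Gradients are verified against central finite
differences in the test suite, and the forward pass against an
independent scalar reimplementation to ~1e-9 relative error.

## Dataset construction

From an activity matrix (regions × tissues, TPM units), a genome FASTA
and pre-flattened exclusion intervals (BED):

* **Housekeeping positives**: regions whose minimum *nonzero* TPM across
  all samples is ≥ 0.08 (all-zero rows carry no evidence and are
  excluded). This selects enhancers active essentially everywhere they
  are detected.
* **Tissue positives**: regions with TPM strictly > 0.8 in the named
  column — the upper quartile of the genome-wide TPM distribution, i.e.
  clear activity in that tissue.
* **Length fixing**: regions shorter than 100 bp are rejected; accepted
  regions become exactly 1000 bp windows centered on the region midpoint
  (`floor((start+end)/2)`). Centering preserves the eRNA
  bidirectional-transcription midpoint; windows overrunning a chromosome
  end are dropped rather than clipped so every sequence has full length.
* **Redundancy reduction**: greedy longest-first clustering at identity
  ≥ 0.8. Identity is the fraction of matching bases in the best ungapped
  offset alignment, normalized by the shorter sequence, with an 8-mer
  prefilter (pairs sharing no 8-mer are taken as below the cutoff).
  Ties in the ordering break by input order, so the result is
  deterministic; re-running on its own output is a no-op. An optional
  pass-through to an external `cd-hit-est` binary is used when one is on
  PATH.
* **Negatives**: windows of the same length drawn uniformly over allowed
  start positions of the intergenic complement (genome minus merged
  exclusions), 10 per positive. Windows containing any ambiguous base
  (N) are rejected and redrawn, avoiding arbitrary N-encoding effects.
  Draws are seed-reproducible; disjointness from every exclusion
  interval is checked in tests with independent interval arithmetic.
* **Splits**: stratified 10/12 train, 1/12 validation, 1/12 test
  (largest-remainder allocation per class), or stratified k-fold.

Coordinates are 0-based half-open (BED convention) throughout; region
ids parse as `chrom:start-end`.

## Evaluation

All indices derive from confusion counts at threshold 0.5 (score ≥
threshold predicts positive): sensitivity, specificity, precision,
accuracy, MCC (zero denominator defined as 0), plus rank-based AUC (the
Mann–Whitney statistic, ties as half-concordant) and AUPRC (descending
score sweep with tied scores grouped).

Two geometric-mean variants exist in the literature and they differ
sharply on 1:10 data: `GM_ss = sqrt(Sens·Spec)` and
`GM_pr = sqrt(Precision·Recall)`. Published benchmark tables for this
task are consistent with `GM_ss` (e.g. Sens 0.499, Spec 0.972 →
`GM_ss` = 0.696 while `GM_pr` ≈ 0.565), so `GM_ss` is the default
reported "GM"; both are computed on every report.

Cross-validation is stratified k-fold (default 5); each fold's model
carves an inner stratified validation split (1/11 of its training
portion) for epoch selection, and fold metrics aggregate by unweighted
mean. Strategy comparison across tissues uses a paired one-sided t-test
on per-tissue GM differences (an unpaired Welch variant is available);
zero-variance differences short-circuit to the degenerate p ∈ {0, 0.5, 1}
by sign.

## Synthetic data

The generator emulates the statistical structure PRS assumes — nothing
more. Positives are i.i.d. background DNA (GC 0.42, human-like) with
position-weight-matrix motifs planted at uniform random positions:

* 3 shared motifs (widths 8–12, consensus weight 0.85, planting
  probability 0.8 each) define the "housekeeping" signal;
* each tissue adds 1 private motif (planting probability 0.9);
* negatives are pure background, 10 per positive;
* defaults: 600 pretraining positives, 200 positives per tissue,
  3 tissues; sequence length 1000 bp, with a 200 bp "fast" profile that
  keeps the motif structure while shrinking compute.

Every record carries machine-readable ground truth (planted motif names
and positions). A synthetic activity matrix exercises the TPM filters:
designated housekeeping rows have all entries in [0.1, 0.79]; designated
tissue-active rows exceed 0.8 in exactly one column while keeping at
least one sub-0.08 nonzero entry elsewhere; all other rows stay below
both cutoffs — so the filters recover the designated rows exactly.

What the generator does **not** model: eRNA expression biology, real TPM
distributions beyond the cutoff structure, nucleosome occupancy, repeat
content, GC isochores, motif syntax/spacing constraints, or chromosomal
context. Passing tests on this data demonstrate that the implementation
learns recoverable sequence signals and that warm-starting transfers
them; they say nothing about accuracy on real genomes.

## Numerical and design choices

* **Optimizer**: Adam, learning rate 1e-3, batch size 64 (configurable).
  L1 subgradients (λ·sign) are added to the training gradient as well as
  the validation objective, making the two consistent.
* **λ1 = λ2 = λ3 = 1e-6** by default: nonzero so the validation
  objective is a true composite, small enough not to dominate
  cross-entropy at desk scale.
* **Dropout 0.2** after pooling, active only in training; inverted
  scaling keeps inference deterministic.
* **Initialization**: Glorot-uniform weights, zero biases,
  seed-reproducible (same seed → bitwise-identical parameters).
* **Pooling** is max pooling, non-overlapping, remainder truncated — the
  DeepBind/Basset-family convention.
* **N bases** encode as all-zero rows (keeps rows binary and pooling
  monotone) rather than 0.25-uniform.
* **No reverse-complement augmentation**: strand symmetry is left to the
  bidirectional recurrence.
* **Retraining updates all parameter groups** by default; a `freeze`
  option restricts updates to everything outside the named groups (the
  output projection always trains). Retraining uses a fixed epoch budget
  with no early stopping — the N-epoch protocol is defined by its epoch
  count — and a validation-selected variant is available by passing a
  validation set.
* **Class imbalance** is handled by plain cross-entropy (no class
  weights) by default; a positive-class weight is configurable. The
  observed low ab-initio sensitivity under imbalance is an expected
  consequence and is exactly the failure mode warm-starting repairs.
* **Pretraining epoch cap**: 100 by default with epoch selection. Desk
  scale: 25 epochs for a standalone pretraining run (held-out AUC > 0.9
  on generator defaults), 10 inside the warm-start comparison, where a
  partially converged pretraining already transfers the shared motifs
  and keeps the five-seed experiment cheap.
* **Scores** are clipped to [1e-12, 1 − 1e-12] so they remain strictly
  inside (0, 1) in floating point; cross-entropy clips identically.
* **Grid search** follows a two-stage protocol on fixed splits: stage 1
  varies filter number × filter length at pooling 3 and fixes the filter
  number with the best validation GM; stage 2 varies filter length ×
  pooling size at that filter number. A full 3-way cross is available.
* **GC cyclic-collector note**: encoding a set allocates one array, not
  one per record, and training promotes long-lived objects before the
  minibatch loop; this is purely a performance measure.

## Desk-scale experiment sizes

The standard comparison (`enhprs.training.prs_benchmark`) uses the fast
200 bp profile with a matched small network (16 filters of length 11,
pooling 8, 16 GRU units per direction): per seed, one pretraining run
(600+6000 sequences, ≤10 epochs with epoch selection) and, per tissue,
warm-start and ab-initio runs of exactly 20 epochs on the tissue's 10/12
training split (200+2000 sequences), scored on the held-out 1/12 test
split. Five seeds × three tissues give 15 paired comparisons. These
sizes were chosen as the smallest at which the warm-start advantage is
reliably detectable.

## Known limitations

* The network is single-convolution-layer by design; deeper CNN stacks
  and attention variants are out of scope.
* The redundancy reducer is not an exact CD-HIT-EST reimplementation
  (identity is ungapped best-offset; CD-HIT's short-word heuristics
  differ in edge cases).
* Full-scale results on real FANTOM5/VISTA data require external
  downloads and long training runs; nothing here asserts them.
* The t-test on per-tissue GM assumes approximately normal paired
  differences; with 15–23 tissues this is an approximation, as in
  common practice.
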