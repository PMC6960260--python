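# enhprs — pretraining–retraining for tissue-specific enhancer prediction

Enhancers are distal cis-regulatory DNA elements, and most act only in
specific cell or tissue types. Sequence-based deep learning separates
enhancers from background DNA well when tens of thousands of examples are
available, but a *single tissue* typically has only a few hundred known
enhancers — far too few to train a network from scratch without severe
overfitting, and (because of the 1:10 class imbalance such datasets use)
the failure mode is a model that predicts "negative" for everything.

`enhprs` implements the **pretraining–retraining strategy (PRS)** for this
problem, for computational biologists working with FANTOM5-style eRNA
activity matrices or any labeled enhancer sequence sets:

1. **Pretrain** one model on the large set of broadly active
   ("housekeeping") enhancers, with validation-based epoch selection;
2. **Retrain** per tissue: warm-start from the pretrained checkpoint and
   train a small fixed budget (20 epochs) on the tissue's own data.

The classifier is a hybrid convolutional/recurrent network over one-hot
DNA:

    Conv(F×m) → ReLU → MaxPool(p) → Dropout → Bi-GRU → Dense(32) → σ

trained on the L1-penalized cross-entropy; epoch selection minimizes the
validation objective

    objective_va = crossentropy_va + λ₁‖M‖₁ + λ₂‖WU‖₁ + λ₃‖WM‖₁

where `M` is the convolution filter bank (learned motif detectors), `WU`
the GRU gate matrices and `WM` the dense-layer weights. The network,
including backpropagation through the bidirectional GRU, is implemented
directly in numpy and verified against finite differences and an
independent scalar forward pass.

The package also provides the full dataset-construction pipeline (TPM
filtering of an activity matrix, 1000 bp length fixing, greedy redundancy
reduction, intergenic negative sampling at 1:10), the imbalanced-
evaluation toolkit (Sens/Spec/Precision/ACC/MCC, both GM variants, AUC,
AUPRC, stratified cross-validation, paired tissue comparisons), and a
synthetic motif-planting generator so everything is testable without
downloads. See `docs/methods.md` for the model and all design choices.

## Worked example

Generate synthetic data (200 bp fast profile: three shared motifs, one
private motif per tissue, 1:10 imbalance), pretrain, then compare a
20-epoch warm start against 20-epoch ab-initio training on one tissue:

```python
from enhprs import (
    ObjectiveConfig, SplitSpec, ab_initio, default_spec, evaluate,
    fast_profile_config, generate_pretraining_set, generate_tissue_set,
    make_splits, predict_scores, pretrain, retrain,
)

spec = default_spec("fast", seed=0)          # 200 bp profile, 3 tissues
cfg = fast_profile_config()                  # 16 filters x 11 bp, pool 8

pre = pretrain(generate_pretraining_set(spec).sequences, cfg,
               ObjectiveConfig(max_epochs=10, seed=0))
print(pre.test_report.tsv_header())
print(pre.test_report.tsv_row("pretraining"))

tissue = generate_tissue_set(spec, "tissue_0").sequences
tr, _va, te = make_splits(tissue, SplitSpec(seed=0))
warm = retrain((pre.run.parameters, cfg), tr, epochs=20,
               obj_cfg=ObjectiveConfig(seed=0))
cold = ab_initio(tr, cfg, epochs=20, obj_cfg=ObjectiveConfig(seed=0))

for name, run in [("warm-start-20", warm), ("ab-initio-20", cold)]:
    rep = evaluate(te.labels, predict_scores(run.parameters, cfg, te))
    print(rep.tsv_row(name))
```

Output:

```
dataset	ACC	AUC	SEN	SPE	MCC	GM
pretraining	0.918	0.890	0.140	0.996	0.308	0.373
warm-start-20	0.956	0.968	0.625	0.988	0.699	0.786
ab-initio-20	0.912	0.692	0.000	1.000	0.000	0.000
```

Reading the rows: the briefly trained pretraining model already ranks
enhancers well (AUC 0.89) but is conservative at the 0.5 threshold. After
20 warm-start epochs on the small tissue set, the model finds 62% of
held-out tissue enhancers at specificity 0.99 (GM 0.79). The ab-initio
baseline given the identical 20-epoch budget collapses to the majority
class — sensitivity 0, GM 0 — despite a deceptively high accuracy of
0.91. That gap is the transfer-learning effect the strategy exists for.

A `enhprs` console script wraps the same operations (`simulate`,
`prepare-pretrain`, `prepare-tissue`, `pretrain`, `retrain`, `ab-initio`,
`grid-search`, `evaluate`, `compare`); every command writes a JSON run
manifest, a JSON-lines training log and an npz checkpoint, and is
byte-identical to the corresponding library call at the same seed.

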