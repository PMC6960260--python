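"""Objective, training loops, and the pretraining–retraining strategy (PRS).

The training loss is mean binary cross-entropy plus L1 penalties on the
three named parameter groups; epoch selection minimizes the *validation*
objective

    objective_va = crossentropy_va + l1*||M||_1 + l2*||WU||_1 + l3*||WM||_1

rather than the training objective, and the returned parameters are the
checkpoint of the best validation epoch — a cheap, effective guard against
overfitting on imbalanced data.

PRS itself: pretrain once, with epoch selection, on the large broadly
active ("housekeeping") enhancer set; then *warm-start* retrain for a
small, fixed number of epochs (20 by default, no early stopping) on each
small tissue-specific set.  The ab-initio baseline trains the same fixed
budget from random initialization.
"""

from __future__ import annotations

import gc
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .datasets import LabeledSequenceSet, SplitSpec, make_splits
from .encoding import EncodedBatch, encode_batch
from .evaluation import EvalReport, evaluate
from .network import (
    GROUP_M,
    GROUP_WM,
    GROUP_WU,
    NetworkConfig,
    NetworkParameters,
    backward,
    build_network,
    forward,
    l1_norms,
    load_checkpoint,
    save_checkpoint,
)

__all__ = [
    "ObjectiveConfig",
    "EpochRecord",
    "TrainingRun",
    "DivergenceError",
    "cross_entropy",
    "objective",
    "train",
    "pretrain",
    "retrain",
    "ab_initio",
    "grid_search",
    "GridSearchResult",
    "predict_scores",
    "stratified_two_way_split",
    "warm_start_experiment",
]

# freeze groups include each group's biases; the output projection is never
# a member, so freezing all three still leaves the output layer trainable
_FREEZE_KEYS = {
    "M": ("conv_W", "conv_b"),
    "WU": ("gru_fw_W", "gru_fw_U", "gru_fw_b", "gru_bw_W", "gru_bw_U", "gru_bw_b"),
    "WM": ("dense_W", "dense_b"),
}
_PENALTY_GROUPS = {"M": GROUP_M, "WU": GROUP_WU, "WM": GROUP_WM}


@dataclass(frozen=True)
class ObjectiveConfig:
    """Loss and optimizer settings.

    The L1 weights default to 1e-6 — small enough not to dominate the
    cross-entropy at desk scale but nonzero so the validation objective is
    a true composite.  Optimization is Adam (adaptive-moment gradient
    descent) with learning rate 1e-3 and minibatches of 64.
    """

    lambda1: float = 1e-6
    lambda2: float = 1e-6
    lambda3: float = 1e-6
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 100
    seed: int = 0
    class_weight_positive: float = 1.0  # plain cross-entropy by default

    def __post_init__(self) -> None:
        if min(self.lambda1, self.lambda2, self.lambda3) < 0:
            raise ValueError("L1 weights must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    @property
    def lambdas(self) -> tuple[float, float, float]:
        return (self.lambda1, self.lambda2, self.lambda3)


class DivergenceError(RuntimeError):
    """Raised when training produces non-finite losses; carries history."""

    def __init__(self, message: str, history: list):
        super().__init__(message)
        self.history = history


@dataclass
class EpochRecord:
    epoch: int
    train_ce: float
    val_ce: float | None = None
    val_objective: float | None = None
    val_report: EvalReport | None = None

    def to_jsonable(self) -> dict:
        d = {"epoch": self.epoch, "train_ce": self.train_ce,
             "val_ce": self.val_ce, "val_objective": self.val_objective}
        if self.val_report is not None:
            d["val_gm"] = self.val_report.gm
            d["val_auc"] = self.val_report.auc
        return d


@dataclass
class TrainingRun:
    """Per-epoch history plus the selected parameters.

    With epoch selection on, ``parameters`` is the checkpoint of the epoch
    minimizing the validation objective (never merely the last epoch), and
    that minimality is asserted at construction.  Fixed-budget runs (the
    retraining protocol) return the final epoch.
    """

    history: list[EpochRecord]
    selected_epoch: int
    parameters: NetworkParameters
    config: NetworkConfig
    provenance: str  # "ab_initio" or "warm_start:<checkpoint id>"
    initial_train_ce: float
    epoch_selection: bool

    def __post_init__(self) -> None:
        if self.history:
            if not (1 <= self.selected_epoch <= len(self.history)):
                raise ValueError("selected_epoch out of range")
        if self.epoch_selection:
            objs = [r.val_objective for r in self.history]
            best = objs[self.selected_epoch - 1]
            if any(o < best for o in objs):
                raise AssertionError(
                    "epoch-selection invariant violated: selected epoch does not "
                    "minimize the validation objective"
                )

    def write_log(self, path: str | Path) -> None:
        """JSON-lines training log, one record per epoch."""
        with open(path, "w") as fh:
            fh.write(json.dumps({
                "provenance": self.provenance,
                "selected_epoch": self.selected_epoch,
                "initial_train_ce": self.initial_train_ce,
                "config": self.config.to_dict(),
            }) + "\n")
            for rec in self.history:
                fh.write(json.dumps(rec.to_jsonable()) + "\n")


def cross_entropy(labels, scores) -> float:
    """Mean negative log-likelihood -(1/n) sum[y log yhat + (1-y) log(1-yhat)]."""
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if labels.size == 0:
        raise ValueError("empty input")
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    s = np.clip(scores, 1e-12, 1.0 - 1e-12)
    return float(-np.mean(labels * np.log(s) + (1.0 - labels) * np.log(1.0 - s)))


def objective(params: NetworkParameters, cfg: NetworkConfig, val_batch: EncodedBatch,
              obj_cfg: ObjectiveConfig) -> float:
    """Validation objective: cross-entropy plus the three L1 penalties."""
    scores = predict_scores(params, cfg, val_batch)
    ce = cross_entropy(val_batch.labels, scores)
    n1, n2, n3 = l1_norms(params)
    return ce + obj_cfg.lambda1 * n1 + obj_cfg.lambda2 * n2 + obj_cfg.lambda3 * n3


def predict_scores(params: NetworkParameters, cfg: NetworkConfig,
                   data: EncodedBatch | LabeledSequenceSet,
                   chunk: int = 128) -> np.ndarray:
    """Deterministic scores for a batch or set, computed in memory-bounded chunks."""
    batch = data if isinstance(data, EncodedBatch) else encode_batch(data)
    out = np.empty(len(batch))
    for lo in range(0, len(batch), chunk):
        idx = np.arange(lo, min(lo + chunk, len(batch)))
        out[idx] = forward(params, cfg, batch.subset(idx), train_mode=False)
    return out


class _Adam:
    def __init__(self, params: NetworkParameters, lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.arrays.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.arrays.items()}
        self.t = 0

    def step(self, params: NetworkParameters, grads: dict[str, np.ndarray],
             frozen: frozenset[str]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            if k in frozen:
                continue
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g * g
            params[k] = params[k] - self.lr * (self.m[k] / bc1) / (
                np.sqrt(self.v[k] / bc2) + self.eps
            )


def _check_disjoint(train_set: LabeledSequenceSet, val_set: LabeledSequenceSet) -> None:
    overlap = set(train_set.ids) & set(val_set.ids)
    if overlap:
        raise ValueError(
            f"validation set shares {len(overlap)} record id(s) with the training set"
        )


def train(
    params_init: NetworkParameters,
    cfg: NetworkConfig,
    train_set: LabeledSequenceSet,
    val_set: LabeledSequenceSet | None,
    obj_cfg: ObjectiveConfig,
    provenance: str = "ab_initio",
    epochs: int | None = None,
    freeze: Iterable[str] = (),
) -> TrainingRun:
    """Minibatch gradient training of the L1-penalized cross-entropy.

    With ``val_set`` given, the validation objective is recorded after
    every epoch and the returned parameters are the checkpoint of the
    epoch minimizing it (epoch selection).  With ``val_set=None`` the run
    is fixed-budget: exactly ``epochs`` epochs, final parameters returned.

    ``freeze`` names parameter groups ("M", "WU", "WM") excluded from
    updates (their biases included); the output projection always trains.
    Reproducible per seed.  Raises :class:`DivergenceError` (history
    attached) on non-finite loss.
    """
    if len(train_set) == 0:
        raise ValueError("empty training set")
    if len(np.unique(train_set.labels)) < 2:
        raise ValueError("training set must contain both classes")
    select = val_set is not None
    if select:
        if len(np.unique(val_set.labels)) < 2:
            raise ValueError("validation set must contain both classes")
        _check_disjoint(train_set, val_set)
        val_batch = encode_batch(val_set)
    n_epochs = obj_cfg.max_epochs if epochs is None else epochs
    bad = set(freeze) - set(_FREEZE_KEYS)
    if bad:
        raise ValueError(f"unknown freeze group(s) {sorted(bad)}; expected M, WU, WM")
    frozen = frozenset(k for g in freeze for k in _FREEZE_KEYS[g])

    params = params_init.copy()
    train_batch = encode_batch(train_set)
    # promote long-lived record objects to the oldest GC generation so the
    # allocation-heavy minibatch loop does not rescan them constantly
    gc.collect()
    rng = np.random.default_rng(obj_cfg.seed)
    dropout_rng = np.random.default_rng(rng.integers(0, 2**31))
    adam = _Adam(params, obj_cfg.learning_rate)
    n = len(train_batch)
    lambdas = dict(zip(("M", "WU", "WM"), obj_cfg.lambdas))
    w_pos = obj_cfg.class_weight_positive

    initial_train_ce = cross_entropy(
        train_batch.labels, predict_scores(params, cfg, train_batch)
    )

    history: list[EpochRecord] = []
    best_obj = np.inf
    best_epoch = 0
    best_params = params.copy()
    for epoch in range(1, n_epochs + 1):
        order = rng.permutation(n)
        epoch_losses = []
        for lo in range(0, n, obj_cfg.batch_size):
            mb = train_batch.subset(order[lo:lo + obj_cfg.batch_size])
            scores, cache = forward(
                params, cfg, mb, train_mode=True, dropout_rng=dropout_rng,
                return_cache=True,
            )
            y = mb.labels
            wts = np.where(y == 1, w_pos, 1.0)
            wmean = wts.mean()
            loss = cross_entropy(y, scores) if w_pos == 1.0 else float(
                -np.mean(wts * (y * np.log(np.clip(scores, 1e-12, 1)) +
                                (1 - y) * np.log(np.clip(1 - scores, 1e-12, 1))))
            )
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite training loss at epoch {epoch}", history
                )
            epoch_losses.append(loss)
            dlogit = wts * (scores - y) / len(mb)
            grads = backward(params, cfg, mb, scores, cache, dlogit)
            for gname, keys in _PENALTY_GROUPS.items():
                lam = lambdas[gname]
                if lam > 0:
                    for k in keys:
                        grads[k] = grads[k] + lam * np.sign(params[k])
            adam.step(params, grads, frozen)

        rec = EpochRecord(epoch=epoch, train_ce=float(np.mean(epoch_losses)))
        if select:
            val_scores = predict_scores(params, cfg, val_batch)
            rec.val_ce = cross_entropy(val_batch.labels, val_scores)
            n1, n2, n3 = l1_norms(params)
            rec.val_objective = rec.val_ce + obj_cfg.lambda1 * n1 + \
                obj_cfg.lambda2 * n2 + obj_cfg.lambda3 * n3
            if not np.isfinite(rec.val_objective):
                raise DivergenceError(
                    f"non-finite validation objective at epoch {epoch}", history
                )
            rec.val_report = evaluate(val_batch.labels.astype(int), val_scores)
            if rec.val_objective < best_obj:
                best_obj = rec.val_objective
                best_epoch = epoch
                best_params = params.copy()
        history.append(rec)

    if select:
        final_params, selected = best_params, best_epoch
    else:
        final_params, selected = params, max(n_epochs, 1)
    final_params.check_finite()
    return TrainingRun(
        history=history,
        selected_epoch=selected if history else 1,
        parameters=final_params,
        config=cfg,
        provenance=provenance,
        initial_train_ce=initial_train_ce,
        epoch_selection=select,
    )


# ---------------------------------------------------------------------------
# PRS stages
# ---------------------------------------------------------------------------

@dataclass
class PretrainResult:
    run: TrainingRun
    test_report: EvalReport
    checkpoint_path: Path | None


def pretrain(
    dataset: LabeledSequenceSet,
    cfg: NetworkConfig,
    obj_cfg: ObjectiveConfig,
    out_path: str | Path | None = None,
    split: SplitSpec | None = None,
) -> PretrainResult:
    """Pretraining stage: split 10/12–1/12–1/12, train with epoch selection,
    evaluate on the held-out test split, write a checkpoint.

    Warns (and proceeds) if the dataset is not at the expected 1:10
    positive:negative ratio.
    """
    labels = dataset.labels
    n_pos, n_neg = int(labels.sum()), int((1 - labels).sum())
    if n_pos == 0 or abs(n_neg - 10 * n_pos) > max(1, n_pos):
        warnings.warn(
            f"pretraining set ratio is {n_pos}:{n_neg}, not the expected 1:10",
            stacklevel=2,
        )
    split = split or SplitSpec(seed=obj_cfg.seed)
    tr, va, te = make_splits(dataset, split)
    params0 = build_network(cfg, seed=obj_cfg.seed)
    run = train(params0, cfg, tr, va, obj_cfg, provenance="ab_initio")
    test_batch = encode_batch(te)
    report = evaluate(
        test_batch.labels.astype(int),
        predict_scores(run.parameters, cfg, test_batch),
    )
    path = None
    if out_path is not None:
        path = Path(out_path)
        save_checkpoint(
            path, run.parameters, cfg,
            meta={"stage": "pretrain", "selected_epoch": run.selected_epoch,
                  "test_gm": report.gm, "test_auc": report.auc},
        )
    return PretrainResult(run=run, test_report=report, checkpoint_path=path)


def _resolve_checkpoint(checkpoint) -> tuple[NetworkParameters, NetworkConfig, str]:
    if isinstance(checkpoint, (str, Path)):
        params, cfg, _meta = load_checkpoint(checkpoint)
        return params, cfg, str(checkpoint)
    params, cfg = checkpoint
    return params, cfg, "in-memory"


def retrain(
    checkpoint,
    tissue_train: LabeledSequenceSet,
    epochs: int = 20,
    freeze: Iterable[str] = (),
    obj_cfg: ObjectiveConfig | None = None,
    val_set: LabeledSequenceSet | None = None,
) -> TrainingRun:
    """Warm-start retraining for exactly ``epochs`` epochs (fixed budget).

    ``checkpoint`` is a path or a ``(params, cfg)`` pair from pretraining.
    There is no early stopping — the N-epoch protocol is defined by its
    epoch count — unless a ``val_set`` is supplied, which switches on
    validation-based epoch selection instead.  ``epochs=0`` returns the
    checkpoint parameters unchanged.
    """
    params, cfg, ckpt_id = _resolve_checkpoint(checkpoint)
    obj_cfg = obj_cfg or ObjectiveConfig()
    if tissue_train.fixed_length != cfg.input_length:
        raise ValueError(
            f"checkpoint expects {cfg.input_length} bp inputs but dataset "
            f"has fixed_length {tissue_train.fixed_length}"
        )
    provenance = f"warm_start:{ckpt_id}"
    if epochs == 0 and val_set is None:
        return TrainingRun(
            history=[], selected_epoch=1, parameters=params.copy(), config=cfg,
            provenance=provenance, initial_train_ce=float("nan"),
            epoch_selection=False,
        )
    if val_set is not None:
        return train(params, cfg, tissue_train, val_set, obj_cfg,
                     provenance=provenance, freeze=freeze)
    return train(params, cfg, tissue_train, None, obj_cfg,
                 provenance=provenance, epochs=epochs, freeze=freeze)


def ab_initio(
    tissue_train: LabeledSequenceSet,
    cfg: NetworkConfig,
    epochs: int,
    obj_cfg: ObjectiveConfig | None = None,
) -> TrainingRun:
    """Fixed-budget training from random initialization (no pretraining)."""
    obj_cfg = obj_cfg or ObjectiveConfig()
    params0 = build_network(cfg, seed=obj_cfg.seed)
    return train(params0, cfg, tissue_train, None, obj_cfg,
                 provenance="ab_initio", epochs=epochs)


# ---------------------------------------------------------------------------
# Hyperparameter grid search
# ---------------------------------------------------------------------------

@dataclass
class GridSearchResult:
    """Per-combination validation GM and AUC, one row per evaluated cell."""

    table: "pd.DataFrame"  # columns: stage, filter_number, filter_length, pool_size, gm, auc
    best_filter_number: int
    best: dict


def grid_search(
    dataset: LabeledSequenceSet,
    obj_cfg: ObjectiveConfig,
    filter_numbers: Sequence[int] = (32, 64, 128, 256),
    filter_lengths: Sequence[int] = tuple(range(5, 26, 2)),
    pool_sizes: Sequence[int] = (3, 5, 8, 11, 14, 17),
    base_cfg: NetworkConfig | None = None,
    full_cross: bool = False,
) -> GridSearchResult:
    """Two-stage hyperparameter search on fixed splits.

    Stage 1 varies filter_number x filter_length at pooling size 3 and
    fixes the filter number whose best cell maximizes validation GM; stage
    2 varies filter_length x pool_size at that filter number (it is never
    re-varied).  ``full_cross=True`` evaluates the complete 3-way product
    instead.  Every cell reports validation GM and AUC.
    """
    import pandas as pd

    if not filter_numbers or not filter_lengths or not pool_sizes:
        raise ValueError("empty hyperparameter grid")
    base = base_cfg or NetworkConfig()
    tr, va, _te = make_splits(dataset, SplitSpec(seed=obj_cfg.seed))
    va_batch = encode_batch(va)

    def eval_cell(fn: int, fl: int, ps: int) -> tuple[float, float]:
        cfg = NetworkConfig(
            filter_number=fn, filter_length=fl, pool_size=ps,
            gru_units_per_direction=base.gru_units_per_direction,
            dense_units=base.dense_units, dropout_rate=base.dropout_rate,
            input_length=dataset.fixed_length,
        )
        run = train(build_network(cfg, obj_cfg.seed), cfg, tr, va, obj_cfg)
        rep = evaluate(
            va_batch.labels.astype(int),
            predict_scores(run.parameters, cfg, va_batch),
        )
        return rep.gm, rep.auc

    rows = []
    if full_cross:
        for fn in filter_numbers:
            for fl in filter_lengths:
                for ps in pool_sizes:
                    gm, auc_ = eval_cell(fn, fl, ps)
                    rows.append(("full", fn, fl, ps, gm, auc_))
        df = pd.DataFrame(rows, columns=["stage", "filter_number", "filter_length",
                                         "pool_size", "gm", "auc"])
        ibest = df["gm"].idxmax()
        best = df.loc[ibest].to_dict()
        return GridSearchResult(table=df, best_filter_number=int(best["filter_number"]),
                                best=best)

    stage1_pool = pool_sizes[0]
    for fn in filter_numbers:
        for fl in filter_lengths:
            gm, auc_ = eval_cell(fn, fl, stage1_pool)
            rows.append(("stage1", fn, fl, stage1_pool, gm, auc_))
    df1 = pd.DataFrame(rows, columns=["stage", "filter_number", "filter_length",
                                      "pool_size", "gm", "auc"])
    best_fn = int(df1.loc[df1["gm"].idxmax(), "filter_number"])

    for fl in filter_lengths:
        for ps in pool_sizes:
            gm, auc_ = eval_cell(best_fn, fl, ps)
            rows.append(("stage2", best_fn, fl, ps, gm, auc_))
    df = pd.DataFrame(rows, columns=["stage", "filter_number", "filter_length",
                                     "pool_size", "gm", "auc"])
    stage2 = df[df.stage == "stage2"]
    best = stage2.loc[stage2["gm"].idxmax()].to_dict()
    return GridSearchResult(table=df, best_filter_number=best_fn, best=best)


# ---------------------------------------------------------------------------
# Splitting helper and the warm-start comparison experiment
# ---------------------------------------------------------------------------

def stratified_two_way_split(
    data: LabeledSequenceSet, val_fraction: float, seed: int
) -> tuple[LabeledSequenceSet, LabeledSequenceSet]:
    """Stratified (train, val) split used for inner epoch selection."""
    labels = data.labels
    rng = np.random.default_rng(seed)
    tr_idx: list[int] = []
    va_idx: list[int] = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        rng.shuffle(idx)
        n_val = max(1, int(round(val_fraction * len(idx))))
        if n_val >= len(idx):
            raise ValueError("val_fraction leaves an empty training class")
        va_idx.extend(idx[:n_val].tolist())
        tr_idx.extend(idx[n_val:].tolist())
    return data.subset(sorted(tr_idx)), data.subset(sorted(va_idx))


def warm_start_experiment(
    dataset_factory: Callable[[int], tuple[LabeledSequenceSet, dict[str, LabeledSequenceSet]]],
    cfg: NetworkConfig,
    pretrain_obj: ObjectiveConfig,
    tissue_obj: ObjectiveConfig,
    retrain_epochs: int = 20,
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
) -> dict:
    """Warm-start vs ab-initio comparison at a fixed epoch budget.

    For each seed, ``dataset_factory(seed)`` supplies a pretraining set and
    per-tissue sets.  The pretrained model (epoch selection) is warm-start
    retrained for ``retrain_epochs`` epochs on each tissue's training
    split; the ab-initio baseline trains the same budget from random
    initialization on the same split.  Both are scored on the tissue's
    held-out test split.  Returns per-run GM and sensitivity for both
    strategies plus their means.
    """
    results = {"warm_gm": [], "ab_gm": [], "warm_sens": [], "ab_sens": [],
               "pretrain_auc": [], "pretrain_gm": [], "per_run": []}
    for seed in seeds:
        pre_set, tissue_sets = dataset_factory(seed)
        pre_obj = ObjectiveConfig(
            lambda1=pretrain_obj.lambda1, lambda2=pretrain_obj.lambda2,
            lambda3=pretrain_obj.lambda3, learning_rate=pretrain_obj.learning_rate,
            batch_size=pretrain_obj.batch_size, max_epochs=pretrain_obj.max_epochs,
            seed=seed,
        )
        pre = pretrain(pre_set, cfg, pre_obj)
        results["pretrain_auc"].append(pre.test_report.auc)
        results["pretrain_gm"].append(pre.test_report.gm)
        for tissue, tset in tissue_sets.items():
            tr, _va, te = make_splits(tset, SplitSpec(seed=seed))
            t_obj = ObjectiveConfig(
                lambda1=tissue_obj.lambda1, lambda2=tissue_obj.lambda2,
                lambda3=tissue_obj.lambda3, learning_rate=tissue_obj.learning_rate,
                batch_size=tissue_obj.batch_size, max_epochs=tissue_obj.max_epochs,
                seed=seed,
            )
            warm = retrain((pre.run.parameters, cfg), tr, epochs=retrain_epochs,
                           obj_cfg=t_obj)
            cold = ab_initio(tr, cfg, epochs=retrain_epochs, obj_cfg=t_obj)
            te_batch = encode_batch(te)
            y = te_batch.labels.astype(int)
            rep_w = evaluate(y, predict_scores(warm.parameters, cfg, te_batch))
            rep_c = evaluate(y, predict_scores(cold.parameters, cfg, te_batch))
            results["warm_gm"].append(rep_w.gm)
            results["ab_gm"].append(rep_c.gm)
            results["warm_sens"].append(rep_w.sens)
            results["ab_sens"].append(rep_c.sens)
            results["per_run"].append({
                "seed": seed, "tissue": tissue,
                "warm": {"gm": rep_w.gm, "sens": rep_w.sens, "auc": rep_w.auc},
                "ab_initio": {"gm": rep_c.gm, "sens": rep_c.sens, "auc": rep_c.auc},
            })
    for key in ("warm_gm", "ab_gm", "warm_sens", "ab_sens", "pretrain_auc", "pretrain_gm"):
        results[f"mean_{key}"] = float(np.mean(results[key]))
    return results


def fast_profile_config() -> NetworkConfig:
    """The desk-scale network used with the 200 bp synthetic profile:
    16 filters of length 11, pooling 8, 16 GRU units per direction."""
    return NetworkConfig(
        filter_number=16, filter_length=11, pool_size=8,
        gru_units_per_direction=16, input_length=200,
    )


def prs_benchmark(seeds: Sequence[int] = (0, 1, 2, 3, 4),
                  retrain_epochs: int = 20,
                  pretrain_max_epochs: int = 10) -> dict:
    """The standard desk-scale PRS comparison on default synthetic data.

    Generates the default fast-profile conditions per seed (600 pretraining
    positives, 3 tissues with 200 positives each, 1:10 ratio, 200 bp) and
    runs :func:`warm_start_experiment` with the fast-profile network.
    """
    from .synthetic import default_spec, generate_pretraining_set, generate_tissue_set

    def factory(seed: int):
        spec = default_spec("fast", seed=seed)
        pre = generate_pretraining_set(spec)
        tissues = {
            t: generate_tissue_set(spec, t).sequences for t in spec.tissue_motifs
        }
        return pre.sequences, tissues

    return warm_start_experiment(
        factory,
        fast_profile_config(),
        pretrain_obj=ObjectiveConfig(max_epochs=pretrain_max_epochs),
        tissue_obj=ObjectiveConfig(),
        retrain_epochs=retrain_epochs,
        seeds=seeds,
    )
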