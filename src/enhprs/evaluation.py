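"""Imbalanced-classification evaluation indices and protocols.

Enhancer datasets are built at a 1:10 positive:negative ratio, so accuracy
alone is uninformative; the indices here follow the standard imbalanced
repertoire: sensitivity, specificity, precision, accuracy, Matthews
correlation coefficient (MCC), geometric mean (GM), ROC AUC and AUPRC.

Two GM variants exist in the literature.  ``gm_ss = sqrt(Sens * Spec)`` is
the balanced-accuracy-style geometric mean and is the default reported
"GM"; ``gm_pr = sqrt(Precision * Recall)`` (the F-measure's geometric
cousin) is also computed.  Both are exposed on every report.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "TissueComparison",
    "confusion",
    "metrics",
    "auc",
    "auprc",
    "evaluate",
    "roc_points",
    "cross_validate",
    "compare_strategies",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN at a stated score threshold."""

    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp


@dataclass
class EvalReport:
    """Threshold metrics plus ranking metrics for one evaluation.

    ``gm`` mirrors ``gm_ss`` (the reported default).  ``auc``/``auprc`` are
    NaN when the report was derived from counts alone.
    """

    sens: float
    spec: float
    precision: float
    acc: float
    mcc: float
    gm_ss: float
    gm_pr: float
    auc: float = float("nan")
    auprc: float = float("nan")
    threshold: float = 0.5
    counts: ConfusionCounts | None = None

    @property
    def gm(self) -> float:
        return self.gm_ss

    def to_json(self) -> str:
        d = asdict(self)
        d["gm"] = self.gm
        return json.dumps(d, indent=2)

    def tsv_row(self, name: str = "") -> str:
        """TSV row in table order: ACC, AUC, SEN, SPE, MCC, GM."""
        vals = [self.acc, self.auc, self.sens, self.spec, self.mcc, self.gm]
        return "\t".join([name] + [f"{v:.3f}" for v in vals])

    @staticmethod
    def tsv_header(name_col: str = "dataset") -> str:
        return "\t".join([name_col, "ACC", "AUC", "SEN", "SPE", "MCC", "GM"])


def _check_scores(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.ndim != 1:
        raise ValueError("labels and scores must be 1-D and of equal length")
    if labels.size == 0:
        raise ValueError("empty input")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    return labels.astype(int), scores


def confusion(labels, scores, threshold: float = 0.5) -> ConfusionCounts:
    """Confusion counts with score >= threshold predicting positive."""
    labels, scores = _check_scores(labels, scores)
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
        threshold=threshold,
    )


def metrics(c: ConfusionCounts) -> EvalReport:
    """Threshold metrics from confusion counts.

    Requires at least one ground-truth positive and one negative.  MCC with
    a zero denominator is defined as 0; precision with no predicted
    positives is defined as 0.
    """
    if c.positives == 0 or c.negatives == 0:
        raise ValueError("metrics require at least one positive and one negative")
    tp, fp, tn, fn = (float(x) for x in (c.tp, c.fp, c.tn, c.fn))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    acc = (tp + tn) / (tp + fp + tn + fn)
    denom = math.sqrt((tp + fn) * (tp + fp) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom > 0 else 0.0
    return EvalReport(
        sens=sens,
        spec=spec,
        precision=precision,
        acc=acc,
        mcc=mcc,
        gm_ss=math.sqrt(sens * spec),
        gm_pr=math.sqrt(precision * sens),
        threshold=c.threshold,
        counts=c,
    )


def auc(labels, scores) -> float:
    """ROC AUC as the Mann–Whitney statistic.

    Equals (#concordant positive–negative pairs + half the ties) / (P*N);
    midranks handle ties exactly.
    """
    labels, scores = _check_scores(labels, scores)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = stats.rankdata(scores)
    pos_rank_sum = float(ranks[labels == 1].sum())
    return (pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def auprc(labels, scores) -> float:
    """Area under the precision–recall step curve.

    Descending-score sweep with tied scores grouped at one operating point;
    the area is the sum of precision times recall increments.  With all
    scores equal this reduces to the prevalence P/(P+N).
    """
    labels, scores = _check_scores(labels, scores)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("AUPRC requires at least one positive")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # group boundaries where the (descending) score changes
    boundaries = np.flatnonzero(np.diff(s) != 0)
    ends = np.append(boundaries, s.size - 1)
    cum_tp = np.cumsum(y)
    cum_n = np.arange(1, s.size + 1)
    tp_at = cum_tp[ends].astype(float)
    n_at = cum_n[ends].astype(float)
    precision = tp_at / n_at
    recall = tp_at / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


def roc_points(labels, scores):
    """(FPR, TPR) operating points of the descending-score sweep."""
    labels, scores = _check_scores(labels, scores)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    ends = np.append(np.flatnonzero(np.diff(s) != 0), s.size - 1)
    tp = np.cumsum(y)[ends]
    fp = (np.arange(1, s.size + 1) - np.cumsum(y))[ends]
    fpr = np.concatenate([[0.0], fp / n_neg])
    tpr = np.concatenate([[0.0], tp / n_pos])
    return fpr, tpr


def evaluate(labels, scores, threshold: float = 0.5) -> EvalReport:
    """Full report: threshold metrics plus AUC and AUPRC."""
    rep = metrics(confusion(labels, scores, threshold))
    rep.auc = auc(labels, scores)
    rep.auprc = auprc(labels, scores)
    return rep


def mean_report(reports: list[EvalReport]) -> EvalReport:
    """Unweighted mean of per-fold metrics."""
    if not reports:
        raise ValueError("no reports to aggregate")
    agg = lambda attr: float(np.mean([getattr(r, attr) for r in reports]))
    return EvalReport(
        sens=agg("sens"), spec=agg("spec"), precision=agg("precision"),
        acc=agg("acc"), mcc=agg("mcc"), gm_ss=agg("gm_ss"), gm_pr=agg("gm_pr"),
        auc=agg("auc"), auprc=agg("auprc"), threshold=reports[0].threshold,
    )


def cross_validate(dataset, cfg, obj_cfg, k: int = 5) -> tuple[EvalReport, list[EvalReport]]:
    """Stratified k-fold cross-validation of the network.

    Each fold's model trains on the other k-1 folds, with an inner
    stratified validation split (one eleventh of the training portion)
    carved out for epoch selection, and is evaluated on the held-out fold.
    Returns the unweighted mean report and the per-fold reports.
    """
    from . import training as _training  # local import to avoid a cycle
    from .datasets import make_kfold
    from .encoding import encode_batch
    from .network import build_network

    folds = make_kfold(dataset, k, seed=obj_cfg.seed)
    reports = []
    for fold_i, test_idx in enumerate(folds):
        test_set = dataset.subset(test_idx)
        if len(np.unique(test_set.labels)) < 2:
            raise ValueError(f"fold {fold_i} contains a single class")
        train_idx = [i for f in folds if f is not test_idx for i in f]
        train_pool = dataset.subset(train_idx)
        tr, va = _training.stratified_two_way_split(
            train_pool, val_fraction=1.0 / 11.0, seed=obj_cfg.seed + fold_i
        )
        params0 = build_network(cfg, seed=obj_cfg.seed + 1000 + fold_i)
        run = _training.train(params0, cfg, tr, va, obj_cfg)
        test_batch = encode_batch(test_set)
        from .network import forward
        scores = forward(run.parameters, cfg, test_batch, train_mode=False)
        reports.append(evaluate(test_batch.labels.astype(int), scores))
    return mean_report(reports), reports


@dataclass
class TissueComparison:
    """Paired per-tissue comparison of two training strategies."""

    gm_a: list[float]
    gm_b: list[float]
    differences: list[float]
    mean_a: float
    mean_b: float
    t_statistic: float
    p_value: float
    paired: bool = True
    degenerate: bool = False

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def compare_strategies(a, b, paired: bool = True) -> TissueComparison:
    """One-sided test of strategy a outperforming strategy b per tissue.

    Default is a paired t-test on the per-tissue differences a - b
    (alternative: mean difference > 0); ``paired=False`` uses Welch's
    unpaired variant.  Zero-variance differences are degenerate: p is 0 or
    1 by the sign of the (constant) difference, 0.5 when a == b exactly.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D and matched in tissue order")
    if a.size < 3:
        raise ValueError("need at least 3 tissues")
    diffs = a - b
    if paired and np.allclose(diffs.std(ddof=1), 0.0):
        d = float(diffs[0])
        if d == 0:
            t_stat, p, degen = 0.0, 0.5, True
        else:
            t_stat = math.inf if d > 0 else -math.inf
            p = 0.0 if d > 0 else 1.0
            degen = True
    elif paired:
        res = stats.ttest_rel(a, b, alternative="greater")
        t_stat, p, degen = float(res.statistic), float(res.pvalue), False
    else:
        res = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
        t_stat, p, degen = float(res.statistic), float(res.pvalue), False
    return TissueComparison(
        gm_a=a.tolist(), gm_b=b.tolist(), differences=diffs.tolist(),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        t_statistic=t_stat, p_value=p, paired=paired, degenerate=degen,
    )
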