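"""High/low expression classification from binding strength.

Genes are split by FPKM quartile: the top 25% are the "high" class, the
bottom 25% the "low" class, the middle half is excluded, so the two classes
are balanced by construction and chance-level balanced accuracy is 0.5.
A soft-margin SVM (RBF kernel) is trained on TFAS features - log(1+A),
z-scored with training-fold statistics only - under stratified 5-fold
cross-validation; performance is scored by

    Sn = TP/(TP+FN),  Sp = TN/(TN+FP),  Acc = (Sn + Sp)/2

averaged over folds. The cross-cell-line prediction difference of a factor
is D_Acc = (Acc_1 - Acc_2) / (Acc_1 + Acc_2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import FunctionTransformer, StandardScaler
from sklearn.svm import SVC

from .tfas import TFASMatrix, pair_pcc

__all__ = [
    "ExpressionLabels",
    "EvalMetrics",
    "PredictionComparison",
    "quartile_labels",
    "evaluate",
    "svm_scan",
    "prediction_difference",
    "correlate_dynamics",
    "select_by_prediction_difference",
]


@dataclass
class ExpressionLabels:
    """Balanced high/low gene classes from FPKM quartiles."""

    labels: dict[str, str]  # gene_id -> "high" | "low"
    fpkm_high_min: float
    fpkm_low_max: float
    n_high: int
    n_low: int

    def gene_ids(self) -> list[str]:
        return list(self.labels)


@dataclass
class EvalMetrics:
    """Confusion counts and the derived Sn / Sp / balanced accuracy."""

    tp: int
    tn: int
    fp: int
    fn: int
    sn: float
    sp: float
    acc: float


@dataclass
class PredictionComparison:
    factor_name: str
    acc_1: float  # accuracy in the first cell line (Acc^G in the reference)
    acc_2: float
    d_acc: float


def quartile_labels(expr: dict[str, float]) -> ExpressionLabels:
    """Label the top FPKM quartile "high" and the bottom quartile "low".

    Genes are ranked by FPKM with ties broken by gene_id (lexicographic) for
    determinism; each class gets ceil(n/4) genes. Degenerate input (all FPKM
    equal) is rejected.
    """
    n = len(expr)
    if n < 4:
        raise ValueError(f"quartile labeling needs >= 4 genes, got {n}")
    values = set(expr.values())
    if len(values) == 1:
        raise ValueError("all FPKM values are equal; quartiles are degenerate")
    count = math.ceil(n / 4)
    ranked = sorted(expr.items(), key=lambda kv: (-kv[1], kv[0]))
    high = ranked[:count]
    low_ranked = sorted(expr.items(), key=lambda kv: (kv[1], kv[0]))
    low = low_ranked[:count]
    labels: dict[str, str] = {}
    for gid, _ in high:
        labels[gid] = "high"
    for gid, _ in low:
        if gid in labels:  # can only happen with pathological tie structure
            raise ValueError(
                "high and low quartiles intersect; FPKM distribution too tied"
            )
        labels[gid] = "low"
    return ExpressionLabels(
        labels=labels,
        fpkm_high_min=min(v for _, v in high),
        fpkm_low_max=max(v for _, v in low),
        n_high=count,
        n_low=count,
    )


def evaluate(tp: int, tn: int, fp: int, fn: int) -> EvalMetrics:
    """Sensitivity, specificity and balanced accuracy from confusion counts."""
    if tp + fn == 0:
        raise ValueError("no positive-class examples (TP + FN = 0)")
    if tn + fp == 0:
        raise ValueError("no negative-class examples (TN + FP = 0)")
    sn = tp / (tp + fn)
    sp = tn / (tn + fp)
    return EvalMetrics(tp=tp, tn=tn, fp=fp, fn=fn, sn=sn, sp=sp, acc=(sn + sp) / 2)


def _make_pipeline(
    c: float, kernel: str, gamma, log_transform: bool
) -> Pipeline:
    steps = []
    if log_transform:
        steps.append(("log1p", FunctionTransformer(np.log1p, validate=True)))
        steps.append(("scale", StandardScaler()))
    steps.append(("svm", SVC(C=c, kernel=kernel, gamma=gamma)))
    return Pipeline(steps)


def svm_scan(
    tfas: TFASMatrix,
    labels: ExpressionLabels,
    feature_sets: Sequence[Sequence[str]],
    folds: int = 5,
    seed: int = 0,
    c: float = 1.0,
    kernel: str = "rbf",
    gamma="auto",
    log_transform: bool = True,
) -> dict[tuple[str, ...], EvalMetrics]:
    """Cross-validated SVM classification for each feature (factor) set.

    For every feature set, genes are restricted to the labeled ones, features
    are log(1+A)-transformed and z-scored inside the per-fold pipeline (so
    scaling statistics come from the training folds only), and an SVC is
    trained per stratified fold. Sn/Sp/Acc are fold averages; confusion
    counts are pooled over folds. gamma="auto" is 1/n_features.
    """
    gene_index = {g: i for i, g in enumerate(tfas.genes)}
    labeled = [g for g in labels.labels if g in gene_index]
    missing = set(labels.labels) - set(labeled)
    if missing:
        raise ValueError(
            f"{len(missing)} labeled genes missing from the TFAS matrix, "
            f"e.g. {sorted(missing)[:3]}"
        )
    rows = np.array([gene_index[g] for g in labeled])
    y = np.array([1 if labels.labels[g] == "high" else 0 for g in labeled])

    results: dict[tuple[str, ...], EvalMetrics] = {}
    for feature_set in feature_sets:
        feats = tuple(feature_set)
        if not feats:
            raise ValueError("empty feature set")
        x = tfas.select(list(feats))[rows]
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        sn_list, sp_list = [], []
        tp = tn = fp = fn = 0
        for train_idx, test_idx in skf.split(x, y):
            pipe = _make_pipeline(c, kernel, gamma, log_transform)
            pipe.fit(x[train_idx], y[train_idx])
            pred = pipe.predict(x[test_idx])
            truth = y[test_idx]
            f_tp = int(np.sum((pred == 1) & (truth == 1)))
            f_tn = int(np.sum((pred == 0) & (truth == 0)))
            f_fp = int(np.sum((pred == 1) & (truth == 0)))
            f_fn = int(np.sum((pred == 0) & (truth == 1)))
            fold_m = evaluate(f_tp, f_tn, f_fp, f_fn)
            sn_list.append(fold_m.sn)
            sp_list.append(fold_m.sp)
            tp += f_tp
            tn += f_tn
            fp += f_fp
            fn += f_fn
        sn = float(np.mean(sn_list))
        sp = float(np.mean(sp_list))
        results[feats] = EvalMetrics(
            tp=tp, tn=tn, fp=fp, fn=fn, sn=sn, sp=sp, acc=(sn + sp) / 2
        )
    return results


def prediction_difference(
    acc_1: float, acc_2: float, factor_name: str = ""
) -> PredictionComparison:
    """Prediction difference index D_Acc = (Acc_1 - Acc_2)/(Acc_1 + Acc_2)."""
    if acc_1 < 0 or acc_2 < 0:
        raise ValueError("accuracies must be nonnegative")
    if acc_1 + acc_2 == 0:
        raise ValueError("D_Acc undefined: both accuracies are zero")
    return PredictionComparison(
        factor_name=factor_name,
        acc_1=acc_1,
        acc_2=acc_2,
        d_acc=(acc_1 - acc_2) / (acc_1 + acc_2),
    )


def correlate_dynamics(
    d_acc_list: Sequence[float], d_signal_list: Sequence[float]
) -> float:
    """Pearson correlation between per-factor D_Acc and D_signal (aligned by
    factor). Returns NaN when either vector is constant."""
    if len(d_acc_list) != len(d_signal_list):
        raise ValueError("D_Acc and D_signal lists must be aligned")
    if len(d_acc_list) < 3:
        raise ValueError("correlation needs at least 3 factors")
    return pair_pcc(
        np.asarray(d_acc_list, dtype=float),
        np.asarray(d_signal_list, dtype=float),
        "d_acc",
        "d_signal",
    ).pcc


def select_by_prediction_difference(
    comparisons: Sequence[PredictionComparison],
    k: int = 10,
    top: bool = True,
) -> list[str]:
    """Rank factors by D_Acc and take k.

    top=True: the k largest with D_Acc > 0; top=False: the k smallest with
    D_Acc < 0. Fewer than k qualifying factors returns all of them.
    """
    if top:
        pool = sorted(
            (pc for pc in comparisons if pc.d_acc > 0),
            key=lambda pc: (-pc.d_acc, pc.factor_name),
        )
    else:
        pool = sorted(
            (pc for pc in comparisons if pc.d_acc < 0),
            key=lambda pc: (pc.d_acc, pc.factor_name),
        )
    return [pc.factor_name for pc in pool[:k]]
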