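"""Evaluation protocol: confusion metrics, top-k accuracy under k-fold
cross-validation, per-kinase 7:3 splits with 1:1 negative sampling, and
ROC / precision-recall curves."""

from __future__ import annotations

import math
from collections.abc import Callable, Sequence
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io_formats import KinaseSubstratePair, PhosphoSite


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Derived confusion-matrix metrics; undefined rates are ``None``."""

    tpr: Optional[float]
    fpr: Optional[float]
    tnr: Optional[float]
    fnr: Optional[float]
    accuracy: float
    precision: Optional[float]
    recall: Optional[float]
    f1: Optional[float]


def confusion_metrics(counts: ConfusionCounts) -> MetricSet:
    """Compute TPR/FPR/TNR/FNR, accuracy, precision, recall and F1.

    F1 is the harmonic mean of precision and recall, equivalently
    ``2*TP / (2*TP + FP + FN)``.
    """
    if counts.total == 0:
        raise ValueError("all confusion counts are zero")
    pos = counts.tp + counts.fn
    neg = counts.tn + counts.fp
    tpr = counts.tp / pos if pos else None
    fnr = counts.fn / pos if pos else None
    tnr = counts.tn / neg if neg else None
    fpr = counts.fp / neg if neg else None
    precision = (
        counts.tp / (counts.tp + counts.fp) if (counts.tp + counts.fp) else None
    )
    denom = 2 * counts.tp + counts.fp + counts.fn
    f1 = 2 * counts.tp / denom if denom else None
    return MetricSet(
        tpr=tpr,
        fpr=fpr,
        tnr=tnr,
        fnr=fnr,
        accuracy=(counts.tp + counts.tn) / counts.total,
        precision=precision,
        recall=tpr,
        f1=f1,
    )


def topk_hit(
    ranked: Sequence[tuple[str, float]] | Sequence[str],
    true_kinase: str,
    k: int,
) -> bool:
    """True iff the true kinase appears within the first k ranked entries."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ids = [r[0] if isinstance(r, tuple) else r for r in ranked[:k]]
    return true_kinase in ids


#: a scorer factory maps training pairs to a per-pair ranking function
ScorerFactory = Callable[
    [Sequence[KinaseSubstratePair]],
    Callable[[KinaseSubstratePair], Sequence[tuple[str, float]]],
]


def kfold_topk_accuracy(
    pairs: Sequence[KinaseSubstratePair],
    scorer: ScorerFactory,
    folds: int = 10,
    k: int = 10,
    seed: int = 0,
) -> list[float]:
    """Top-k accuracy per fold of a seeded k-fold cross-validation.

    For each fold the scorer is re-trained on the remaining pairs only, and
    fold accuracy is the fraction of held-out pairs whose true kinase lands
    in the top k of the ranking for that pair's site.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if len(pairs) < folds:
        raise ValueError("need at least one pair per fold")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    fold_indices = np.array_split(order, folds)
    accuracies: list[float] = []
    for test_idx in fold_indices:
        if len(test_idx) == 0:
            raise ValueError("a fold has zero test pairs")
        test_set = set(int(i) for i in test_idx)
        train = [p for i, p in enumerate(pairs) if i not in test_set]
        rank_fn = scorer(train)
        hits = 0
        for i in test_idx:
            pair = pairs[int(i)]
            ranked = rank_fn(pair)
            hits += topk_hit(ranked, pair.kinase_id, k)
        accuracies.append(hits / len(test_idx))
    return accuracies


@dataclass(frozen=True)
class SplitSpec:
    """Parameters of an evaluation split."""

    protocol: str = "per_kinase"  # or "kfold"
    folds: int = 10
    train_fraction: float = 0.7
    neg_ratio: float = 1.0  # negatives per positive in the test set
    seed: int = 0

    def __post_init__(self) -> None:
        if self.protocol not in ("per_kinase", "kfold"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class LabeledSplit:
    train: list[PhosphoSite]
    test: list[tuple[PhosphoSite, int]]  # (site, label) with 1 = positive
    spec: SplitSpec = field(default_factory=SplitSpec)
    n_neg_other: int = 0
    n_neg_nonphospho: int = 0


def per_kinase_split(
    sites: Sequence[PhosphoSite],
    other_kinase_sites: Sequence[PhosphoSite],
    nonphospho_windows: Sequence[PhosphoSite],
    spec: SplitSpec | None = None,
) -> LabeledSplit:
    """Split one kinase's sites 7:3 and draw a 1:1 negative test set.

    Test size is ``floor((1 - train_fraction) * n)``; negatives are sampled
    without replacement, half from other kinases' sites and half from
    non-phosphorylated S/T/Y windows when both pools suffice, otherwise
    topped up from the larger pool.
    """
    spec = spec or SplitSpec()
    n = len(sites)
    if n < 2:
        raise ValueError("need at least 2 positive sites to split")
    rng = np.random.default_rng(spec.seed)
    n_test = math.floor((1 - spec.train_fraction) * n)
    if n_test < 1:
        raise ValueError("split leaves no positive test sites")
    order = rng.permutation(n)
    test_pos = [sites[i] for i in order[:n_test]]
    train = [sites[i] for i in order[n_test:]]

    n_neg = round(spec.neg_ratio * n_test)
    pool_other = list(other_kinase_sites)
    pool_non = list(nonphospho_windows)
    if len(pool_other) + len(pool_non) < n_neg:
        raise ValueError(
            f"insufficient negatives: need {n_neg}, have "
            f"{len(pool_other) + len(pool_non)}"
        )
    n_other = min(n_neg - n_neg // 2, len(pool_other))
    n_non = min(n_neg - n_other, len(pool_non))
    n_other = n_neg - n_non  # top up from the other-kinase pool if needed
    neg: list[PhosphoSite] = []
    if n_other:
        idx = rng.choice(len(pool_other), size=n_other, replace=False)
        neg.extend(pool_other[i] for i in idx)
    if n_non:
        idx = rng.choice(len(pool_non), size=n_non, replace=False)
        neg.extend(pool_non[i] for i in idx)
    test = [(s, 1) for s in test_pos] + [(s, 0) for s in neg]
    return LabeledSplit(
        train=train,
        test=test,
        spec=spec,
        n_neg_other=n_other,
        n_neg_nonphospho=n_non,
    )


def planted_topk_accuracies(
    dataset,
    top_k: int = 10,
    seed: int = 0,
    min_sites: int = 4,
    alpha: float = 0.5,
    k_fraction: float = 0.075,
) -> dict[str, float | int]:
    """Top-k recovery of planted kinases on a synthetic dataset.

    Splits each kinase's pairs 7:3, trains the network and sequence models
    on the train portion only, and measures top-k accuracy of the
    network-only, sequence-only and combined rankings (plus top-1 accuracy
    of the PWM alone) on the held-out sites.  Returns the accuracies, the
    test size and the chance level (1 / number of kinases).  ``min_sites``
    defaults lower than on curated data because synthetic corpora are
    smaller.
    """
    import warnings

    from .combined_scoring import build_score_vector, combine, rank_kinases_overall
    from .io_formats import filter_trainable_kinases
    from .network_scoring import (
        build_affinity_graph,
        build_integrated_network,
        rank_kinases_network,
    )
    from .sequence_scoring import TrainingCorpus, train_pwm_models

    by_kinase: dict[str, list[KinaseSubstratePair]] = {}
    for pair in dataset.pairs:
        by_kinase.setdefault(pair.kinase_id, []).append(pair)
    rng = np.random.default_rng(seed)
    train_pairs: list[KinaseSubstratePair] = []
    test_pairs: list[KinaseSubstratePair] = []
    for kinase in sorted(by_kinase):
        pairs = by_kinase[kinase]
        n_test = math.floor(0.3 * len(pairs))
        order = rng.permutation(len(pairs))
        test_pairs.extend(pairs[i] for i in order[:n_test])
        train_pairs.extend(pairs[i] for i in order[n_test:])
    if not test_pairs:
        raise ValueError("no held-out pairs; increase sites_per_kinase")

    net = build_integrated_network(train_pairs, dataset.ppi)
    affinity = build_affinity_graph(net)
    trainable = filter_trainable_kinases(train_pairs, min_sites=min_sites)
    if not trainable:
        raise ValueError(f"no kinase has more than {min_sites} training sites")
    models = train_pwm_models(trainable, alpha=alpha)
    corpus = TrainingCorpus.from_sites(trainable)

    hits = {"network": 0, "sequence": 0, "overall": 0, "pwm_top1": 0}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for pair in test_pairs:
            ranked_net = rank_kinases_network(affinity, pair.site, top_k)
            hits["network"] += topk_hit(ranked_net, pair.kinase_id, top_k)
            sv = build_score_vector(
                pair.site, affinity, models, corpus, k_fraction=k_fraction
            )
            combine(sv, candidates="intersection")
            ranked_seq = rank_kinases_overall(sv, mode="sequence", top_k=top_k)
            hits["sequence"] += topk_hit(ranked_seq, pair.kinase_id, top_k)
            ranked_all = rank_kinases_overall(sv, mode="overall", top_k=top_k)
            hits["overall"] += topk_hit(ranked_all, pair.kinase_id, top_k)
            ranked_pwm = rank_kinases_overall(sv, mode="pwm", top_k=top_k)
            hits["pwm_top1"] += topk_hit(ranked_pwm, pair.kinase_id, 1)
    n = len(test_pairs)
    return {
        "network": hits["network"] / n,
        "sequence": hits["sequence"] / n,
        "overall": hits["overall"] / n,
        "pwm_top1": hits["pwm_top1"] / n,
        "n_test": n,
        "chance": 1.0 / len(by_kinase),
    }


@dataclass
class CurveReport:
    roc: list[tuple[float, float]]  # (FPR, TPR)
    auroc: float
    pr: list[tuple[float, float]]  # (recall, precision)
    auprc: float


def roc_pr_curves(scores: Sequence[tuple[float, int]]) -> CurveReport:
    """ROC and PR curves from (score, label) pairs via a threshold sweep.

    Thresholds are the unique scores in descending order with ties grouped;
    areas are trapezoidal.  Raises on single-class input.
    """
    labels = {lab for _, lab in scores}
    if labels != {0, 1}:
        raise ValueError("both classes must be present (labels 0 and 1)")
    arr = sorted(scores, key=lambda t: -t[0])
    n_pos = sum(lab for _, lab in arr)
    n_neg = len(arr) - n_pos
    roc = [(0.0, 0.0)]
    pr: list[tuple[float, float]] = []
    tp = fp = 0
    i = 0
    while i < len(arr):
        j = i
        while j < len(arr) and arr[j][0] == arr[i][0]:
            tp += arr[j][1]
            fp += 1 - arr[j][1]
            j += 1
        i = j
        roc.append((fp / n_neg, tp / n_pos))
        pr.append((tp / n_pos, tp / (tp + fp)))
    # anchor PR at recall 0 with the first threshold's precision
    pr.insert(0, (0.0, pr[0][1]))
    auroc = float(np.trapezoid([t for _, t in roc], [f for f, _ in roc]))
    auprc = float(np.trapezoid([p for _, p in pr], [r for r, _ in pr]))
    return CurveReport(roc=roc, auroc=auroc, pr=pr, auprc=auprc)
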