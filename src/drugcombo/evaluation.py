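"""Repeated 5-fold cross-validation, ROC curves and F1-based threshold selection.

Only the positives (approved combinations) are folded: they are randomly split
into ``n_folds`` near-equal groups, the model is trained on the remaining
folds and the held-out fold is scored. There are no verified negative
examples, so every background drug pair that is not an approved combination
serves as a negative in every fold (performance is therefore, if anything,
underestimated). The whole procedure is repeated ``n_repeats`` times and
averaged: ROC curves vertically at a fixed false-positive-rate grid, the
F1-versus-threshold curve at a fixed threshold grid. The operating threshold
for future predictions is the one maximizing mean F1, ties going to the larger
threshold (fewer predictions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .datamodel import (
    CombinationSet,
    DEFAULT_KINDS,
    DrugAnnotations,
    DrugPair,
    FeatureKind,
)
from .featurepairs import DEFAULT_PSEUDOCOUNT, build_background, enumerate_feature_pairs
from .integration import CombinationModel

logger = logging.getLogger(__name__)

INTEGRATED = "integrated"
FPR_GRID = np.linspace(0.0, 1.0, 101)


def f1(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class CVConfig:
    n_folds: int = 5
    n_repeats: int = 10
    kinds: Tuple[FeatureKind, ...] = DEFAULT_KINDS
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        self.kinds = tuple(FeatureKind(k) for k in self.kinds)


ScoredPair = Tuple[DrugPair, float, Dict[FeatureKind, float], int]


@dataclass
class CVResult:
    config: CVConfig
    #: (repeat, fold) -> list of (pair, combined score, per-kind scores, label)
    per_repeat_fold: Dict[Tuple[int, int], List[ScoredPair]]
    #: curve name (kind value or "integrated") -> (fpr grid, mean tpr)
    roc: Dict[str, Tuple[np.ndarray, np.ndarray]]
    #: curve name -> mean AUROC across repeats
    auroc: Dict[str, float]
    #: rows (threshold, mean precision, mean recall, mean F1)
    f1_curve: List[Tuple[float, float, float, float]]
    selected_threshold: float
    selected_f1: float
    #: per-kind and combined mean fraction of validation positives with any annotation
    coverage: Dict[str, float] = field(default_factory=dict)


def make_folds(combos: CombinationSet, n_folds: int, seed: int) -> List[CombinationSet]:
    """Randomly partition the positives into near-equal disjoint folds.

    Fold sizes differ by at most one; the split is deterministic given the seed.
    """
    pairs = sorted(combos.pairs)
    if len(pairs) < n_folds:
        raise ValueError(f"cannot split {len(pairs)} combinations into {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    base, extra = divmod(len(pairs), n_folds)
    folds: List[CombinationSet] = []
    start = 0
    for i in range(n_folds):
        size = base + (1 if i < extra else 0)
        idx = order[start : start + size]
        folds.append(combos.subset(pairs[j] for j in idx))
        start += size
    return folds


def select_threshold(
    f1_curve: Sequence[Tuple[float, float, float, float]]
) -> Tuple[float, float]:
    """Threshold with maximal F1; ties resolved toward the larger threshold."""
    if not f1_curve:
        raise ValueError("empty F1 curve")
    best_t, best_f1 = None, -1.0
    for threshold, _p, _r, score in f1_curve:
        if score > best_f1 or (score == best_f1 and threshold > best_t):
            best_t, best_f1 = threshold, score
    return float(best_t), float(best_f1)


def _fold_pr_counts(
    scores_pos: np.ndarray, scores_neg: np.ndarray, thresholds: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized precision/recall/F1 of the rule `score >= threshold` per threshold."""
    pos = np.sort(scores_pos)
    neg = np.sort(scores_neg)
    tp = len(pos) - np.searchsorted(pos, thresholds, side="left")
    fp = len(neg) - np.searchsorted(neg, thresholds, side="left")
    predicted = tp + fp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(predicted > 0, tp / np.maximum(predicted, 1), 0.0)
        recall = tp / len(pos) if len(pos) else np.zeros_like(tp, dtype=float)
        denom = precision + recall
        f1s = np.where(denom > 0, 2 * precision * recall / np.maximum(denom, 1e-300), 0.0)
    return precision, recall, f1s


def run_cv(
    combos: CombinationSet, annotations: DrugAnnotations, config: CVConfig
) -> CVResult:
    """Repeated n-fold cross-validation of the feature-integration predictor.

    For each repeat and fold the enrichment tables and precision curves are
    fit on the training folds only; the validation positives (label 1) and all
    never-positive background pairs (label 0) are then scored. Emits per-kind
    single-source ROC curves alongside the integrated one.
    """
    background = build_background(combos)
    negatives = sorted(background - combos.pairs)
    rng = np.random.default_rng(config.seed)
    repeat_seeds = rng.integers(0, 2**31 - 1, size=config.n_repeats)

    per_repeat_fold: Dict[Tuple[int, int], List[ScoredPair]] = {}
    curve_names = [k.value for k in config.kinds] + [INTEGRATED]
    repeat_pooled: List[Dict[str, Tuple[np.ndarray, np.ndarray]]] = []
    coverage_acc: Dict[str, List[float]] = {name: [] for name in curve_names}

    for repeat, fold_seed in enumerate(repeat_seeds):
        folds = make_folds(combos, config.n_folds, int(fold_seed))
        pooled: Dict[str, Tuple[List[float], List[int]]] = {
            name: ([], []) for name in curve_names
        }
        for fold_idx, fold in enumerate(folds):
            train = combos.subset(combos.pairs - fold.pairs)
            model = CombinationModel(config.kinds, config.pseudocount).fit(train, annotations)
            scored: List[ScoredPair] = []
            val_pairs = sorted(fold.pairs)
            for pair, label in [(p, 1) for p in val_pairs] + [(p, 0) for p in negatives]:
                cs = model.score_pair(pair)
                scored.append((pair, cs.combined, dict(cs.per_kind), label))
            per_repeat_fold[(repeat, fold_idx)] = scored

            kind_has_info = {
                kind: any(
                    enumerate_feature_pairs(p, annotations, kind) for p in val_pairs
                )
                for kind in config.kinds
            }
            for kind in config.kinds:
                name = kind.value
                if not kind_has_info[kind]:
                    logger.warning(
                        "repeat %d fold %d: no validation positive carries %s features; "
                        "fold skipped in the %s ROC curve",
                        repeat, fold_idx, name, name,
                    )
                    continue
                scores, labels = pooled[name]
                scores.extend(row[2][kind] for row in scored)
                labels.extend(row[3] for row in scored)
            scores, labels = pooled[INTEGRATED]
            scores.extend(row[1] for row in scored)
            labels.extend(row[3] for row in scored)

            n_val = len(val_pairs)
            for kind in config.kinds:
                covered = sum(
                    1 for p in val_pairs if enumerate_feature_pairs(p, annotations, kind)
                )
                coverage_acc[kind.value].append(covered / n_val if n_val else 0.0)
            covered_any = sum(
                1
                for p in val_pairs
                if any(enumerate_feature_pairs(p, annotations, k) for k in config.kinds)
            )
            coverage_acc[INTEGRATED].append(covered_any / n_val if n_val else 0.0)

        repeat_pooled.append(
            {
                name: (np.asarray(scores), np.asarray(labels))
                for name, (scores, labels) in pooled.items()
            }
        )

    roc: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    auroc: Dict[str, float] = {}
    for name in curve_names:
        tprs, aucs = [], []
        for pooled in repeat_pooled:
            scores, labels = pooled[name]
            if len(scores) == 0 or labels.sum() in (0, len(labels)):
                continue
            fpr, tpr, _ = roc_curve(labels, scores)
            tprs.append(np.interp(FPR_GRID, fpr, tpr))
            aucs.append(roc_auc_score(labels, scores))
        if tprs:
            roc[name] = (FPR_GRID.copy(), np.mean(tprs, axis=0))
            auroc[name] = float(np.mean(aucs))

    # F1 curve: evaluate score >= theta on a common grid of observed scores + {0, 1}
    observed = {0.0, 1.0}
    for pooled in repeat_pooled:
        observed.update(np.unique(pooled[INTEGRATED][0]).tolist())
    thresholds = np.array(sorted(observed))
    p_acc, r_acc, f_acc = [], [], []
    for (repeat, fold_idx), scored in sorted(per_repeat_fold.items()):
        combined = np.array([row[1] for row in scored])
        labels = np.array([row[3] for row in scored])
        p, r, fs = _fold_pr_counts(combined[labels == 1], combined[labels == 0], thresholds)
        p_acc.append(p)
        r_acc.append(r)
        f_acc.append(fs)
    mean_p = np.mean(p_acc, axis=0)
    mean_r = np.mean(r_acc, axis=0)
    mean_f = np.mean(f_acc, axis=0)
    f1_curve = [
        (float(t), float(p), float(r), float(fv))
        for t, p, r, fv in zip(thresholds, mean_p, mean_r, mean_f)
    ]
    threshold, best_f1 = select_threshold(f1_curve)

    coverage = {name: float(np.mean(vals)) for name, vals in coverage_acc.items() if vals}
    return CVResult(
        config=config,
        per_repeat_fold=per_repeat_fold,
        roc=roc,
        auroc=auroc,
        f1_curve=f1_curve,
        selected_threshold=threshold,
        selected_f1=best_f1,
        coverage=coverage,
    )
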