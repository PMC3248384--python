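"""Precision-curve calibration and noisy-OR integration across data sources.

Enrichment scores from one feature kind are converted into a drug-pair
confidence via the training-set *precision curve*: every background drug pair
is represented by its best (maximum) feature-pair score, and for each distinct
best score ``s``

    precision(s) = |{pairs with best score >= s} ∩ training combinations|
                   / |{pairs with best score >= s}| .

The confidence a source ``k`` lends a drug pair is the maximum precision
attained at the score of any of its feature pairs (0 when the pair carries no
information from that source). Per-source confidences are combined noisy-OR
style:

    P(i, j) = 1 - prod_k (1 - P_k(i, j)),

so independent sources complement each other and any certain source is
absorbing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .datamodel import (
    CombinationSet,
    DEFAULT_KINDS,
    DrugAnnotations,
    DrugPair,
    FeatureKind,
    FeaturePair,
)
from .featurepairs import (
    DEFAULT_PSEUDOCOUNT,
    EnrichmentTable,
    build_background,
    build_enrichment_table,
    enumerate_feature_pairs,
)

logger = logging.getLogger(__name__)


@dataclass
class PrecisionCurve:
    """Mapping from score thresholds to training-set precision for one kind.

    ``thresholds`` are strictly decreasing; ``n_predicted`` (drug pairs with
    best score >= threshold) is non-decreasing along the list.
    """

    kind: FeatureKind
    thresholds: np.ndarray
    precisions: np.ndarray
    n_predicted: np.ndarray

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.precisions = np.asarray(self.precisions, dtype=float)
        self.n_predicted = np.asarray(self.n_predicted, dtype=int)
        if np.any(np.diff(self.thresholds) >= 0):
            raise ValueError("precision-curve thresholds must be strictly decreasing")
        if np.any((self.precisions < 0) | (self.precisions > 1)):
            raise ValueError("precisions must lie in [0, 1]")

    def precision_at(self, score: float) -> float:
        """Precision of the prediction set {best score >= ``score``}.

        Evaluates the stored step function: the point with the smallest
        threshold still >= ``score``. A score above every stored threshold
        has an empty prediction set and yields 0 (no training support).
        """
        # thresholds descending: count how many are >= score
        k = int(np.searchsorted(-self.thresholds, -score, side="right"))
        if k == 0:
            return 0.0
        return float(self.precisions[k - 1])

    def to_rows(self) -> List[Tuple[str, float, float, int]]:
        return [
            (self.kind.value, float(t), float(p), int(n))
            for t, p, n in zip(self.thresholds, self.precisions, self.n_predicted)
        ]


def best_feature_score(
    pair: DrugPair, annotations: DrugAnnotations, table: EnrichmentTable
) -> Optional[float]:
    """Maximum enrichment score over the drug pair's feature pairs; None if none scored."""
    scores = [
        table.entries[fp].score
        for fp in enumerate_feature_pairs(pair, annotations, table.kind)
        if fp in table.entries
    ]
    return max(scores) if scores else None


def build_precision_curve(
    training_combos: CombinationSet,
    background: Set[DrugPair],
    annotations: DrugAnnotations,
    table: EnrichmentTable,
) -> PrecisionCurve:
    """Precision at every distinct best-score threshold over the background.

    The table must have been built from ``training_combos`` only, so that the
    curve is an honest training-set calibration (no validation leakage).
    """
    if not background:
        raise ValueError("background is empty; precision curve undefined")
    best: List[Tuple[float, bool]] = []
    for pair in background:
        score = best_feature_score(pair, annotations, table)
        if score is not None:
            best.append((score, pair in training_combos.pairs))
    if not best:
        return PrecisionCurve(table.kind, np.empty(0), np.empty(0), np.empty(0, dtype=int))

    scores = np.array([s for s, _ in best])
    labels = np.array([hit for _, hit in best], dtype=float)
    order = np.argsort(-scores, kind="stable")
    scores, labels = scores[order], labels[order]
    cum_hits = np.cumsum(labels)
    n_pred = np.arange(1, len(scores) + 1)
    # keep the last occurrence of each distinct score: the full >= s set
    is_last = np.append(scores[1:] != scores[:-1], True)
    thresholds = scores[is_last]
    precisions = cum_hits[is_last] / n_pred[is_last]
    return PrecisionCurve(table.kind, thresholds, precisions, n_pred[is_last])


def feature_confidence(
    pair: DrugPair,
    annotations: DrugAnnotations,
    table: EnrichmentTable,
    curve: PrecisionCurve,
) -> float:
    """Per-source confidence: max precision over the pair's scored feature pairs.

    Feature pairs unseen in training carry no information and contribute 0.
    """
    best = 0.0
    for fp in enumerate_feature_pairs(pair, annotations, table.kind):
        entry = table.entries.get(fp)
        if entry is None:
            logger.debug("feature pair %s unseen in training; contributes 0", fp)
            continue
        best = max(best, curve.precision_at(entry.score))
    return best


def integrate_confidence(per_kind: Mapping[FeatureKind, float]) -> float:
    """Noisy-OR aggregation: 1 - prod(1 - P_k). Missing sources contribute 0."""
    combined = 1.0
    for kind, value in per_kind.items():
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"confidence for {kind} out of [0, 1]: {value}")
        combined *= 1.0 - value
    return 1.0 - combined


@dataclass(frozen=True)
class ConfidenceScore:
    """Per-source and integrated confidence that two drugs combine effectively."""

    pair: DrugPair
    per_kind: Mapping[FeatureKind, float]
    combined: float


@dataclass
class CombinationModel:
    """A trained model: per-kind enrichment tables plus precision curves.

    Fit on a combination set and annotations; scoring a drug pair evaluates
    each source's precision-calibrated confidence and integrates them.
    """

    kinds: Tuple[FeatureKind, ...] = DEFAULT_KINDS
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    tables: Dict[FeatureKind, EnrichmentTable] = field(default_factory=dict)
    curves: Dict[FeatureKind, PrecisionCurve] = field(default_factory=dict)
    background: Set[DrugPair] = field(default_factory=set)
    annotations: Optional[DrugAnnotations] = None

    def fit(self, combos: CombinationSet, annotations: DrugAnnotations) -> "CombinationModel":
        self.kinds = tuple(FeatureKind(k) for k in self.kinds)
        self.annotations = annotations
        self.background = build_background(combos)
        for kind in self.kinds:
            table = build_enrichment_table(
                combos, annotations, kind, self.pseudocount, self.background
            )
            self.tables[kind] = table
            self.curves[kind] = build_precision_curve(combos, self.background, annotations, table)
        return self

    def score_pair(
        self, pair: DrugPair, kinds: Optional[Sequence[FeatureKind]] = None
    ) -> ConfidenceScore:
        if self.annotations is None:
            raise RuntimeError("model is not fitted")
        for drug in pair:
            if drug not in self.annotations:
                raise KeyError(f"drug {drug!r} unknown to the model's annotations")
        use = tuple(FeatureKind(k) for k in (kinds or self.kinds))
        unknown = set(use) - set(self.kinds)
        if unknown:
            raise ValueError(f"kinds not trained: {sorted(k.value for k in unknown)}")
        per_kind = {
            kind: feature_confidence(pair, self.annotations, self.tables[kind], self.curves[kind])
            for kind in use
        }
        return ConfidenceScore(pair, per_kind, integrate_confidence(per_kind))

    def top_feature_pairs(self, pair: DrugPair, kind: FeatureKind) -> Tuple[FeaturePair, ...]:
        """The feature pair(s) attaining the pair's per-kind confidence."""
        if self.annotations is None:
            raise RuntimeError("model is not fitted")
        kind = FeatureKind(kind)
        table, curve = self.tables[kind], self.curves[kind]
        scored = [
            (curve.precision_at(table.entries[fp].score), fp)
            for fp in enumerate_feature_pairs(pair, self.annotations, kind)
            if fp in table.entries
        ]
        if not scored:
            return ()
        best = max(conf for conf, _ in scored)
        return tuple(sorted(fp for conf, fp in scored if conf == best))


def fit_model(
    combos: CombinationSet,
    annotations: DrugAnnotations,
    kinds: Sequence[FeatureKind] = DEFAULT_KINDS,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> CombinationModel:
    """Convenience constructor: fit a :class:`CombinationModel` in one call."""
    return CombinationModel(tuple(kinds), pseudocount).fit(combos, annotations)


def score_pair(
    pair: DrugPair, model: CombinationModel, kinds: Optional[Sequence[FeatureKind]] = None
) -> ConfidenceScore:
    """Functional form of :meth:`CombinationModel.score_pair`."""
    return model.score_pair(pair, kinds)
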