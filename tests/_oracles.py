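"""Independent brute-force reference implementations used only by the tests.

Every function here recomputes a quantity by direct enumeration, without using
the package's optimized code paths, so that the tests compare two independent
routes to the same answer.
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import Dict, Iterable, List, Sequence, Set, Tuple

from drugcombo.datamodel import (
    CombinationSet,
    DrugAnnotations,
    DrugPair,
    FeatureKind,
    FeaturePair,
)


def brute_count_feature_pairs(
    pairs: Iterable[DrugPair], annotations: DrugAnnotations, kind: FeatureKind
) -> Dict[FeaturePair, int]:
    """Triple loop over (drug pair, feature of a, feature of b); presence counting."""
    counts: Dict[FeaturePair, int] = {}
    for pair in pairs:
        seen: Set[Tuple[str, str]] = set()
        for x in annotations.get(pair.a, kind):
            for y in annotations.get(pair.b, kind):
                key = (min(x, y), max(x, y))
                if key not in seen:
                    seen.add(key)
                    fp = FeaturePair(kind, key[0], key[1])
                    counts[fp] = counts.get(fp, 0) + 1
    return counts


def brute_enrichment_scores(
    combos: CombinationSet,
    annotations: DrugAnnotations,
    kind: FeatureKind,
    pseudocount: float,
) -> Dict[FeaturePair, float]:
    """Directly evaluate the log2 pseudocounted frequency-ratio over the background."""
    drugs = sorted({d for p in combos.pairs for d in p})
    background = [DrugPair(a, b) for a, b in combinations(drugs, 2)]
    bg_counts = brute_count_feature_pairs(background, annotations, kind)
    comb_counts = brute_count_feature_pairs(sorted(combos.pairs), annotations, kind)
    n_bg_total = sum(
        1 for p in background
        if annotations.get(p.a, kind) and annotations.get(p.b, kind)
    )
    n_comb_total = sum(
        1 for p in combos.pairs
        if annotations.get(p.a, kind) and annotations.get(p.b, kind)
    )
    scores = {}
    for fp, n_bg in bg_counts.items():
        n_comb = comb_counts.get(fp, 0)
        scores[fp] = math.log2(
            ((n_comb + pseudocount) / (n_comb_total + pseudocount))
            / ((n_bg + pseudocount) / (n_bg_total + pseudocount))
        )
    return scores


def brute_best_score(
    pair: DrugPair,
    annotations: DrugAnnotations,
    kind: FeatureKind,
    scores: Dict[FeaturePair, float],
):
    best = None
    for x in annotations.get(pair.a, kind):
        for y in annotations.get(pair.b, kind):
            fp = FeaturePair(kind, x, y)
            if fp in scores and (best is None or scores[fp] > best):
                best = scores[fp]
    return best


def brute_precision_curve(
    combos: CombinationSet,
    background: Sequence[DrugPair],
    annotations: DrugAnnotations,
    kind: FeatureKind,
    scores: Dict[FeaturePair, float],
) -> List[Tuple[float, float, int]]:
    """(threshold, precision, n_predicted) at every distinct best score, descending."""
    best = {}
    for pair in background:
        s = brute_best_score(pair, annotations, kind, scores)
        if s is not None:
            best[pair] = s
    out = []
    for s in sorted(set(best.values()), reverse=True):
        predicted = [p for p, v in best.items() if v >= s]
        hits = sum(1 for p in predicted if p in combos.pairs)
        out.append((s, hits / len(predicted), len(predicted)))
    return out


def brute_confidence(
    pair: DrugPair,
    annotations: DrugAnnotations,
    kind: FeatureKind,
    scores: Dict[FeaturePair, float],
    curve: List[Tuple[float, float, int]],
) -> float:
    """Max over the pair's feature pairs of the precision at that score."""
    best = 0.0
    for x in annotations.get(pair.a, kind):
        for y in annotations.get(pair.b, kind):
            fp = FeaturePair(kind, x, y)
            if fp not in scores:
                continue
            s = scores[fp]
            eligible = [p for t, p, _ in curve if t >= s]
            if eligible:
                best = max(best, eligible[-1])
    return best


def brute_co_combined(combos: CombinationSet) -> Dict[DrugPair, Set[str]]:
    """Triple loop over drug triples."""
    drugs = sorted({d for p in combos.pairs for d in p})
    out: Dict[DrugPair, Set[str]] = {}
    for a in drugs:
        for b in drugs:
            if a >= b:
                continue
            for z in drugs:
                if z in (a, b):
                    continue
                if DrugPair(a, z) in combos.pairs and DrugPair(b, z) in combos.pairs:
                    out.setdefault(DrugPair(a, b), set()).add(z)
    return out


def brute_fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided exact p by exhaustive hypergeometric enumeration at fixed margins."""
    n = a + b + c + d
    row1 = a + b
    col1 = a + c

    def pmf(k: int) -> float:
        return (
            math.comb(col1, k)
            * math.comb(n - col1, row1 - k)
            / math.comb(n, row1)
        )

    p_obs = pmf(a)
    lo = max(0, row1 - (n - col1))
    hi = min(row1, col1)
    # standard convention: sum tables no more probable than the observed one
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-9))
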