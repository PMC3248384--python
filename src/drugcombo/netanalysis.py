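"""Descriptive analyses of the combination corpus.

* drug-feature network construction for export (drug-drug edges for approved
  combinations carrying an enriched feature pattern, plus drug-feature edges
  for the best-scoring pattern of each combination);
* co-combined drug pairs (two drugs approved in combination with a common
  third drug) and the exact test of whether they share features more often
  than other drug pairs;
* a chemical-similarity sanity check on co-combined pairs;
* the historical timeline of whether newly approved combinations target
  protein pairs already targeted by earlier combinations;
* rank correlations between the per-source best feature-pair scores of
  approved combinations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations as iter_combinations
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    CombinationSet,
    DrugAnnotations,
    DrugPair,
    FeatureKind,
    FeaturePair,
    SimilarityTable,
)
from .featurepairs import EnrichmentTable, enumerate_feature_pairs
from .io import Edge

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoCombinedPair:
    """Two drugs each approved in combination with at least one common partner."""

    pair: DrugPair
    witnesses: FrozenSet[str]
    is_combination: bool  # the pair itself is also an approved combination


def co_combined_pairs(combos: CombinationSet) -> Set[CoCombinedPair]:
    """All pairs of drugs sharing a combination partner, with their witnesses."""
    graph = nx.Graph()
    graph.add_edges_from((p.a, p.b) for p in combos.pairs)
    found: Dict[DrugPair, Set[str]] = {}
    for witness in graph.nodes:
        partners = sorted(graph.neighbors(witness))
        for a, b in iter_combinations(partners, 2):
            found.setdefault(DrugPair(a, b), set()).add(witness)
    return {
        CoCombinedPair(pair, frozenset(wit), pair in combos.pairs)
        for pair, wit in found.items()
    }


def _feature_edge_property(kind: FeatureKind) -> str:
    # proteins (and pathway-style molecular features) use dp; therapy/indication use da
    if kind in (FeatureKind.TARGET, FeatureKind.MAIN_TARGET, FeatureKind.PATHWAY):
        return "dp"
    return "da"


def build_drug_feature_network(
    combos: CombinationSet,
    annotations: DrugAnnotations,
    kind: FeatureKind,
    table: EnrichmentTable,
    threshold: float,
) -> List[Edge]:
    """Edge list of the drug-feature network for enriched combinations.

    A combination contributes a ``dd`` edge when its best feature-pair score of
    ``kind`` reaches ``threshold``; each drug is then linked to its feature(s)
    of the best-scoring pattern(s) (``dp``/``da``; ``d_m`` when the feature is
    among the drug's main targets).
    """
    kind = FeatureKind(kind)
    prop = _feature_edge_property(kind)
    edges: Set[Edge] = set()
    for pair in sorted(combos.pairs):
        fa = annotations.get(pair.a, kind)
        fb = annotations.get(pair.b, kind)
        routes = []  # (score, drug->feature assignments)
        for x in fa:
            for y in fb:
                entry = table.entries.get(FeaturePair(kind, x, y))
                if entry is not None:
                    routes.append((entry.score, x, y))
        if not routes:
            continue
        best = max(score for score, _, _ in routes)
        if best < threshold:
            continue
        edges.add((pair.a, pair.b, "dd"))
        for score, x, y in routes:
            if score != best:
                continue
            for drug, feature in ((pair.a, x), (pair.b, y)):
                drug_prop = prop
                if prop == "dp" and feature in annotations.get(drug, FeatureKind.MAIN_TARGET):
                    drug_prop = "d_m"
                edges.add((drug, feature, drug_prop))
    return sorted(edges)


@dataclass(frozen=True)
class SharedFeatureResult:
    """2x2 exact-test result: co-combined membership vs sharing a feature."""

    n_shared_cocombined: int      # a: co-combined pairs sharing >= 1 feature
    n_unshared_cocombined: int    # b: co-combined pairs sharing none
    n_shared_other: int           # c: other pairs sharing >= 1 feature
    n_unshared_other: int         # d: other pairs sharing none
    odds_ratio: float
    p_value: float

    @property
    def table(self) -> Tuple[Tuple[int, int], Tuple[int, int]]:
        return (
            (self.n_shared_cocombined, self.n_unshared_cocombined),
            (self.n_shared_other, self.n_unshared_other),
        )


def shared_feature_enrichment(
    cocombined: Iterable[CoCombinedPair],
    all_pairs: Iterable[DrugPair],
    annotations: DrugAnnotations,
    kind: FeatureKind,
) -> SharedFeatureResult:
    """Fisher's exact test: do co-combined drugs share features unusually often?

    The comparison stratum is every unordered pair in ``all_pairs`` that is not
    co-combined; "sharing" means a non-empty intersection of the two drugs'
    feature-token sets of ``kind``. The two-sided p-value is the hypergeometric
    sum over tables at fixed margins with probability <= the observed table's.
    """
    kind = FeatureKind(kind)
    co_pairs = {c.pair for c in cocombined}
    other = set(all_pairs) - co_pairs

    def shares(pair: DrugPair) -> bool:
        return bool(annotations.get(pair.a, kind) & annotations.get(pair.b, kind))

    a = sum(1 for p in co_pairs if shares(p))
    b = len(co_pairs) - a
    c = sum(1 for p in other if shares(p))
    d = len(other) - c
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        raise ValueError(f"degenerate 2x2 table (an empty margin): {((a, b), (c, d))}")
    odds = (a * d) / (b * c) if b * c else (0.0 if a == 0 else float("inf"))
    _, p_value = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return SharedFeatureResult(a, b, c, d, float(odds), float(p_value))


def novelty_timeline(
    combos: CombinationSet,
    annotations: DrugAnnotations,
    baseline_year: int,
) -> pd.DataFrame:
    """Per-year counts of combinations re-using earlier target pairs vs novel ones.

    Combinations with year <= ``baseline_year`` seed the set of seen target
    pairs and are not counted. A later combination is a *repeat* when at least
    one of its target pairs was already targeted by a strictly earlier
    combination (or the baseline); same-year combinations are classified
    together against the strictly-earlier set only, so the result is invariant
    to ordering within a year. Combinations without a year, or without any
    target pair, are skipped with a warning.
    """
    dated: Dict[int, List[DrugPair]] = {}
    for pair in sorted(combos.pairs):
        year = combos.year.get(pair)
        if year is None:
            logger.warning("combination %s-%s has no approval year; skipped", pair.a, pair.b)
            continue
        fps = enumerate_feature_pairs(pair, annotations, FeatureKind.TARGET)
        if not fps:
            logger.info("combination %s-%s has no target pairs; skipped", pair.a, pair.b)
            continue
        dated.setdefault(year, []).append(pair)

    seen: Set[FeaturePair] = set()
    rows = []
    for year in sorted(dated):
        pairs = dated[year]
        fps_per_pair = {
            p: enumerate_feature_pairs(p, annotations, FeatureKind.TARGET) for p in pairs
        }
        if year <= baseline_year:
            for fps in fps_per_pair.values():
                seen |= fps
            continue
        n_repeat = sum(1 for fps in fps_per_pair.values() if fps & seen)
        n_novel = len(pairs) - n_repeat
        rows.append((year, n_repeat, n_novel))
        for fps in fps_per_pair.values():
            seen |= fps

    frame = pd.DataFrame(rows, columns=["year", "n_repeat", "n_novel"])
    if len(frame):
        frame["cum_repeat"] = frame["n_repeat"].cumsum()
        frame["cum_novel"] = frame["n_novel"].cumsum()
        total = frame["cum_repeat"] + frame["cum_novel"]
        frame["cum_frac_repeat"] = frame["cum_repeat"] / total
    else:
        frame["cum_repeat"] = frame["cum_novel"] = frame["cum_frac_repeat"] = []
    return frame


def similarity_check(
    cocombined: Iterable[CoCombinedPair],
    sims: SimilarityTable,
    cutoff: float = 0.6,
) -> Tuple[int, int, int]:
    """(n_total, n_above, n_unknown): co-combined pairs with similarity > cutoff.

    The comparison is strict; pairs absent from the similarity table are
    counted as unknown, never as dissimilar.
    """
    pairs = [c.pair for c in cocombined]
    known = [(p, sims.get(p)) for p in pairs]
    n_unknown = sum(1 for _, s in known if s is None)
    n_above = sum(1 for _, s in known if s is not None and s > cutoff)
    return len(pairs), n_above, n_unknown


def feature_correlation(
    combos: CombinationSet,
    annotations: DrugAnnotations,
    tables: Mapping[FeatureKind, EnrichmentTable],
) -> pd.DataFrame:
    """Spearman rank correlations between per-source best scores of combinations.

    For each feature kind, every approved combination is represented by the
    highest enrichment score among its feature pairs (missing information is
    excluded pairwise). Cells with fewer than 3 common observations are NaN.
    """
    if len(tables) < 2:
        raise ValueError("need at least two feature kinds for a correlation analysis")
    kinds = sorted(tables, key=lambda k: k.value)
    pairs = sorted(combos.pairs)
    vectors = {}
    for kind in kinds:
        table = tables[kind]
        values = []
        for pair in pairs:
            scores = [
                table.entries[fp].score
                for fp in enumerate_feature_pairs(pair, annotations, kind)
                if fp in table.entries
            ]
            values.append(max(scores) if scores else np.nan)
        vectors[kind] = np.array(values)

    names = [k.value for k in kinds]
    out = pd.DataFrame(np.eye(len(kinds)), index=names, columns=names)
    for i, ki in enumerate(kinds):
        for j, kj in enumerate(kinds):
            if j <= i:
                continue
            x, y = vectors[ki], vectors[kj]
            mask = ~(np.isnan(x) | np.isnan(y))
            if mask.sum() < 3:
                rho = np.nan
            else:
                rho = stats.spearmanr(x[mask], y[mask]).statistic
            out.iloc[i, j] = out.iloc[j, i] = rho
    return out
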