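"""Feature-pair enumeration, background construction and enrichment scoring.

A drug pair is represented, per feature kind, by the Cartesian product of the
two drugs' feature sets, canonicalized to unordered :class:`FeaturePair` items.
Each feature pair is scored by comparing its relative frequency among approved
combinations against its frequency in the *background set* — all unordered
pairs of drugs that appear in at least one approved combination:

    score(f1, f2) = log2( ((n_comb + c) / (N_comb + c)) /
                          ((n_bg   + c) / (N_bg   + c)) )

where ``n_comb``/``n_bg`` count the drug pairs (combinations / background)
whose representation contains the feature pair, ``N_comb``/``N_bg`` count drug
pairs contributing at least one feature pair of the kind, and ``c > 0`` is a
pseudocount keeping every score finite. Each drug pair contributes presence
(0/1), not multiplicity: the drug pair is the sampling unit. Only the rank
order of scores matters downstream (precision calibration), so any monotone
frequency-ratio variant would yield identical predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, FrozenSet, Iterable, Iterator, List, Optional, Sequence, Set, Tuple

from .datamodel import CombinationSet, DrugAnnotations, DrugPair, FeatureKind, FeaturePair

DEFAULT_PSEUDOCOUNT = 1.0


def enumerate_feature_pairs(
    pair: DrugPair, annotations: DrugAnnotations, kind: FeatureKind
) -> FrozenSet[FeaturePair]:
    """All feature pairs of ``kind`` representing the drug pair.

    The canonicalized Cartesian product of the two drugs' feature sets; empty
    when either drug carries no features of the kind. Raises ``KeyError`` for
    a drug absent from the annotations entirely.
    """
    for drug in pair:
        if drug not in annotations:
            raise KeyError(f"drug {drug!r} not present in annotations")
    fa = annotations.get(pair.a, kind)
    fb = annotations.get(pair.b, kind)
    return frozenset(FeaturePair(FeatureKind(kind), x, y) for x in fa for y in fb)


def build_background(combos: CombinationSet) -> Set[DrugPair]:
    """All unordered pairs of drugs involved in at least one known combination.

    This is the reference set for enrichment; it is a superset of the
    combination pairs themselves. Size is n(n-1)/2 for n distinct drugs.
    """
    if not combos.pairs:
        raise ValueError("combination set is empty; background undefined")
    drugs = sorted(combos.drugs())
    return {DrugPair(a, b) for a, b in combinations(drugs, 2)}


def count_feature_pairs(
    pairs: Iterable[DrugPair], annotations: DrugAnnotations, kind: FeatureKind
) -> Dict[FeaturePair, int]:
    """Presence counts: each drug pair contributes 1 to each of its distinct feature pairs."""
    counts: Dict[FeaturePair, int] = {}
    for pair in pairs:
        for fp in enumerate_feature_pairs(pair, annotations, kind):
            counts[fp] = counts.get(fp, 0) + 1
    return counts


def enrichment_score(
    n_comb: int,
    n_bg: int,
    N_comb: int,
    N_bg: int,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """Log2 ratio of pseudocounted relative frequencies (combinations vs background)."""
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be > 0, got {pseudocount}")
    if N_comb <= 0 or N_bg <= 0:
        raise ValueError("totals N_comb and N_bg must be positive")
    if n_comb < 0 or n_comb > n_bg:
        raise ValueError(f"need 0 <= n_comb <= n_bg, got n_comb={n_comb}, n_bg={n_bg}")
    freq_comb = (n_comb + pseudocount) / (N_comb + pseudocount)
    freq_bg = (n_bg + pseudocount) / (N_bg + pseudocount)
    return math.log2(freq_comb / freq_bg)


@dataclass(frozen=True)
class EnrichmentEntry:
    n_comb: int
    n_bg: int
    score: float


@dataclass
class EnrichmentTable:
    """Per-kind counts and enrichment scores for every background feature pair.

    ``n_comb_total`` / ``n_bg_total`` are the numbers of combination and
    background drug pairs contributing at least one feature pair of the kind.
    Iteration yields feature pairs by descending score with lexicographic
    tie-breaking, so repeated iteration is deterministic.
    """

    kind: FeatureKind
    entries: Dict[FeaturePair, EnrichmentEntry] = field(default_factory=dict)
    n_comb_total: int = 0
    n_bg_total: int = 0
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def score(self, fp: FeaturePair) -> Optional[float]:
        entry = self.entries.get(fp)
        return None if entry is None else entry.score

    def ranked(self) -> List[Tuple[FeaturePair, EnrichmentEntry]]:
        return sorted(self.entries.items(), key=lambda kv: (-kv[1].score, kv[0].f1, kv[0].f2))

    def __iter__(self) -> Iterator[Tuple[FeaturePair, EnrichmentEntry]]:
        return iter(self.ranked())

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self, path, header: Sequence[str] = ()) -> None:
        """Serialize as TSV (kind, f1, f2, n_comb, n_bg, score)."""
        with open(path, "w", encoding="utf-8") as fh:
            for line in header:
                fh.write(f"# {line}\n")
            fh.write(f"# totals\t{self.n_comb_total}\t{self.n_bg_total}\t{self.pseudocount}\n")
            for fp, entry in self.ranked():
                fh.write(
                    f"{self.kind.value}\t{fp.f1}\t{fp.f2}\t"
                    f"{entry.n_comb}\t{entry.n_bg}\t{entry.score:.10g}\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "EnrichmentTable":
        entries: Dict[FeaturePair, EnrichmentEntry] = {}
        kind: Optional[FeatureKind] = None
        totals = (0, 0)
        pseudocount = DEFAULT_PSEUDOCOUNT
        with open(path, encoding="utf-8") as fh:
            for raw in fh:
                line = raw.rstrip("\n")
                if line.startswith("# totals\t"):
                    _, nc, nb, ps = line.split("\t")
                    totals = (int(nc), int(nb))
                    pseudocount = float(ps)
                    continue
                if not line.strip() or line.startswith("#"):
                    continue
                kind_tok, f1, f2, n_comb, n_bg, score = line.split("\t")
                kind = FeatureKind.parse(kind_tok)
                entries[FeaturePair(kind, f1, f2)] = EnrichmentEntry(
                    int(n_comb), int(n_bg), float(score)
                )
        if kind is None:
            raise ValueError(f"{path}: empty enrichment table has no feature kind")
        return cls(kind, entries, totals[0], totals[1], pseudocount)


def build_enrichment_table(
    combos: CombinationSet,
    annotations: DrugAnnotations,
    kind: FeatureKind,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: Optional[Set[DrugPair]] = None,
) -> EnrichmentTable:
    """Count and score every feature pair occurring in the background.

    The background defaults to :func:`build_background` of ``combos``; an
    explicit background may be supplied when several tables must share one
    (e.g. during cross-validation, where the training set defines the model).
    """
    kind = FeatureKind(kind)
    if background is None:
        background = build_background(combos)

    bg_counts: Dict[FeaturePair, int] = {}
    n_bg_total = 0
    for pair in sorted(background):
        fps = enumerate_feature_pairs(pair, annotations, kind)
        if fps:
            n_bg_total += 1
        for fp in fps:
            bg_counts[fp] = bg_counts.get(fp, 0) + 1

    comb_counts: Dict[FeaturePair, int] = {}
    n_comb_total = 0
    for pair in sorted(combos.pairs):
        fps = enumerate_feature_pairs(pair, annotations, kind)
        if fps:
            n_comb_total += 1
        for fp in fps:
            comb_counts[fp] = comb_counts.get(fp, 0) + 1

    entries: Dict[FeaturePair, EnrichmentEntry] = {}
    for fp, n_bg in bg_counts.items():
        n_comb = comb_counts.get(fp, 0)
        # the pseudocounted ratio stays finite even when no combination carries
        # the kind (n_comb_total == 0): every pair is then background-only
        freq_comb = (n_comb + pseudocount) / (n_comb_total + pseudocount)
        freq_bg = (n_bg + pseudocount) / (n_bg_total + pseudocount)
        entries[fp] = EnrichmentEntry(n_comb, n_bg, math.log2(freq_comb / freq_bg))

    return EnrichmentTable(kind, entries, n_comb_total, n_bg_total, pseudocount)
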