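"""Screening candidate drug pairs for novel combinations.

The candidate universe is every unordered pair of drugs already involved in
some approved combination, minus the approved pairs themselves and minus any
pair touching a user-supplied exclusion list (e.g. drug classes whose
combination mechanisms are already well charted and would dominate the
output). A model trained on all approved combinations scores each candidate;
pairs whose integrated confidence reaches the operating threshold are emitted,
ranked by descending confidence, each carrying the per-source evidence and the
feature pair(s) responsible for it.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, FrozenSet, Iterable, List, Mapping, Sequence, Set, Tuple

from .datamodel import (
    CombinationSet,
    DEFAULT_KINDS,
    DrugAnnotations,
    DrugPair,
    FeatureKind,
    FeaturePair,
)
from .featurepairs import DEFAULT_PSEUDOCOUNT
from .integration import CombinationModel, fit_model

DEFAULT_THRESHOLD = 0.4


@dataclass(frozen=True)
class PredictionRecord:
    pair: DrugPair
    combined: float
    per_kind: Mapping[FeatureKind, float]
    #: per kind, the feature pair(s) attaining the per-kind confidence
    top_feature_pairs: Mapping[FeatureKind, Tuple[FeaturePair, ...]]


def candidate_universe(
    combos: CombinationSet, exclusions: Iterable[str] = ()
) -> Set[DrugPair]:
    """All candidate pairs of combination drugs that are not yet combinations.

    Pairs involving an excluded drug are dropped.
    """
    exclusions = set(exclusions)
    drugs = sorted(combos.drugs() - exclusions)
    return {
        DrugPair(a, b) for a, b in combinations(drugs, 2)
    } - combos.pairs


def predict(
    combos: CombinationSet,
    annotations: DrugAnnotations,
    threshold: float = DEFAULT_THRESHOLD,
    kinds: Sequence[FeatureKind] = DEFAULT_KINDS,
    exclusions: Iterable[str] = (),
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> List[PredictionRecord]:
    """Train on all known combinations and emit candidates above threshold.

    Records are sorted by descending combined confidence, then lexicographic
    pair order. Per-kind evidence is reported even when an individual source
    is weak — only the combined score gates emission.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    model = fit_model(combos, annotations, kinds, pseudocount)
    records: List[PredictionRecord] = []
    for pair in sorted(candidate_universe(combos, exclusions)):
        cs = model.score_pair(pair)
        if cs.combined >= threshold:
            records.append(
                PredictionRecord(
                    pair=pair,
                    combined=cs.combined,
                    per_kind=dict(cs.per_kind),
                    top_feature_pairs={
                        kind: model.top_feature_pairs(pair, kind) for kind in model.kinds
                    },
                )
            )
    records.sort(key=lambda r: (-r.combined, r.pair))
    return records


def read_exclusions(path) -> Set[str]:
    """One drug identifier per line; '#' comments and blank lines ignored."""
    out: Set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out


def write_predictions(records: Sequence[PredictionRecord], path,
                      kinds: Sequence[FeatureKind] = DEFAULT_KINDS,
                      header: Sequence[str] = ()) -> None:
    """TSV: drug_a, drug_b, combined, per-kind confidences, top evidence per kind."""
    kinds = tuple(FeatureKind(k) for k in kinds)
    with open(path, "w", encoding="utf-8") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        cols = ["drug_a", "drug_b", "combined"]
        cols += [f"conf_{k.value}" for k in kinds]
        cols += [f"top_{k.value}" for k in kinds]
        fh.write("# " + "\t".join(cols) + "\n")
        for rec in records:
            row = [rec.pair.a, rec.pair.b, f"{rec.combined:.6g}"]
            row += [f"{rec.per_kind.get(k, 0.0):.6g}" for k in kinds]
            for k in kinds:
                tops = rec.top_feature_pairs.get(k, ())
                row.append(";".join(f"{fp.f1}|{fp.f2}" for fp in tops))
            fh.write("\t".join(row) + "\n")
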