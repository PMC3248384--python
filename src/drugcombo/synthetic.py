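"""Seeded generator of synthetic annotation + combination datasets.

The generator emulates the statistical structure the prediction method relies
on: a minority of feature pairs is strongly over-represented among approved
combinations relative to the background of all drug pairs. Drugs receive
random feature sets per kind (token popularity is skewed, so common features
create realistic background noise, but every token is guaranteed a minimum
number of carrier drugs so that no feature pair is an uninformative
singleton); a handful of *planted* feature pairs is chosen per kind among
moderately rare observed pairs, and drug pairs are sampled as combinations
with probability proportional to ``enrichment_strength ** (number of planted
pairs they contain)``, mixed with a fraction of uniformly random (noise)
combinations. A subset of the sampled positives can be withheld for recovery
tests. Everything is deterministic given the seed.

The defaults mirror the study conditions at desk scale: 60 drugs, 184
combinations (so a 5-fold split has validation folds of about 37), the three
integrated feature kinds (targets, third-level ATC codes, indications), and
per-kind annotation coverage of 75% of drugs, emulating incomplete real-world
annotation sources.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from itertools import combinations as iter_combinations
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional, Set, Tuple

import numpy as np

from .datamodel import (
    CombinationSet,
    DrugAnnotations,
    DrugPair,
    FeatureKind,
    FeaturePair,
    SimilarityTable,
)
from . import io as dcio

TOKEN_PREFIX = {
    FeatureKind.TARGET: "P",
    FeatureKind.MAIN_TARGET: "M",
    FeatureKind.ATC3: "A",
    FeatureKind.INDICATION: "I",
    FeatureKind.PATHWAY: "W",
    FeatureKind.SIDE_EFFECT: "S",
}

_DEFAULT_KINDS = (FeatureKind.TARGET, FeatureKind.ATC3, FeatureKind.INDICATION)


@dataclass
class SynthConfig:
    n_drugs: int = 60
    kinds: Tuple[FeatureKind, ...] = _DEFAULT_KINDS
    #: vocabulary size per kind, sized so tokens recur across drugs
    vocab_sizes: Dict[FeatureKind, int] = field(
        default_factory=lambda: {
            FeatureKind.TARGET: 20,
            FeatureKind.ATC3: 12,
            FeatureKind.INDICATION: 14,
        }
    )
    #: inclusive (lo, hi) number of features per annotated drug
    features_per_drug: Dict[FeatureKind, Tuple[int, int]] = field(
        default_factory=lambda: {
            FeatureKind.TARGET: (2, 4),
            FeatureKind.ATC3: (1, 2),
            FeatureKind.INDICATION: (2, 3),
        }
    )
    #: fraction of drugs annotated per kind (annotation sources are incomplete)
    coverage: Dict[FeatureKind, float] = field(
        default_factory=lambda: {k: 0.75 for k in _DEFAULT_KINDS}
    )
    #: every token is used by at least this many drugs (when feasible)
    min_token_usage: int = 4
    n_planted: int = 5
    #: each planted feature pair consists of two dedicated tokens carried by
    #: this many drugs each, so its background carrier set is small enough for
    #: the sampled combinations to cover it
    planted_token_usage: int = 3
    enrichment_strength: float = 50.0
    n_combos: int = 184
    noise_frac: float = 0.1
    heldout_frac: float = 0.1
    year_range: Optional[Tuple[int, int]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.kinds = tuple(FeatureKind(k) for k in self.kinds)
        self.vocab_sizes = {FeatureKind(k): int(v) for k, v in self.vocab_sizes.items()}
        self.features_per_drug = {
            FeatureKind(k): (int(lo), int(hi)) for k, (lo, hi) in self.features_per_drug.items()
        }
        self.coverage = {FeatureKind(k): float(v) for k, v in self.coverage.items()}
        if self.n_drugs < 2 or self.n_combos < 1 or self.n_planted < 0:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.noise_frac <= 1.0:
            raise ValueError(f"noise_frac must lie in [0, 1], got {self.noise_frac}")
        if not 0.0 <= self.heldout_frac < 1.0:
            raise ValueError(f"heldout_frac must lie in [0, 1), got {self.heldout_frac}")
        if self.enrichment_strength < 1.0:
            raise ValueError("enrichment_strength must be >= 1")


@dataclass
class SyntheticDataset:
    annotations: DrugAnnotations
    combos: CombinationSet
    planted: Dict[FeatureKind, Set[FeaturePair]]
    heldout_positives: Set[DrugPair]
    similarity: SimilarityTable
    config: SynthConfig


def _assign_features(
    rng: np.random.Generator,
    drugs: List[str],
    kind: FeatureKind,
    config: SynthConfig,
) -> Dict[str, FrozenSet[str]]:
    """Deal tokens to the covered drugs with a usage floor plus skewed extras."""
    vocab_size = config.vocab_sizes[kind]
    vocab = [f"{TOKEN_PREFIX[kind]}{i:03d}" for i in range(vocab_size)]
    lo, hi = config.features_per_drug[kind]
    cov = config.coverage.get(kind, 1.0)
    n_annotated = max(2, int(round(cov * len(drugs))))
    annotated = sorted(rng.choice(drugs, size=n_annotated, replace=False))

    demand = rng.integers(lo, hi + 1, size=n_annotated)
    total = int(demand.sum())
    floor = min(config.min_token_usage, total // vocab_size)
    multiset: List[str] = [tok for tok in vocab for _ in range(floor)]
    remaining = total - len(multiset)
    if remaining > 0:
        weights = 1.0 / (np.arange(vocab_size) + 1.0) ** 0.8
        weights /= weights.sum()
        extras = rng.choice(vocab_size, size=remaining, replace=True, p=weights)
        multiset.extend(vocab[i] for i in extras)
    multiset = list(rng.permutation(multiset))

    out: Dict[str, FrozenSet[str]] = {}
    start = 0
    for drug, k in zip(annotated, demand):
        tokens = frozenset(multiset[start : start + int(k)])  # within-drug dups collapse
        out[drug] = tokens
        start += int(k)
    return out


def _pair_feature_pairs(
    features: Mapping[str, FrozenSet[str]], kind: FeatureKind, a: str, b: str
) -> FrozenSet[FeaturePair]:
    fa = features.get(a, frozenset())
    fb = features.get(b, frozenset())
    return frozenset(FeaturePair(kind, x, y) for x in fa for y in fb)


def _plant_tokens(
    rng: np.random.Generator,
    features: Dict[str, FrozenSet[str]],
    kind: FeatureKind,
    config: SynthConfig,
) -> Set[FeaturePair]:
    """Add dedicated planted tokens to a few annotated drugs; return the pairs.

    Each planted feature pair is built from two fresh tokens appended to the
    kind's vocabulary, carried by ``planted_token_usage`` drugs each (disjoint
    drug sets within a pair), so the pair occurs in a small, known set of
    background drug pairs.
    """
    annotated = sorted(features)
    usage = config.planted_token_usage
    needed = 2 * usage * config.n_planted
    if needed > len(annotated):
        raise ValueError(
            f"planting {config.n_planted} pairs at planted_token_usage={usage} needs "
            f"{needed} annotated drugs for {kind.value}, have {len(annotated)}"
        )
    # disjoint drug sets across all planted tokens of the kind, so no drug pair
    # carries a cross-pair of planted tokens and hitchhiking is minimized
    chosen = rng.choice(annotated, size=needed, replace=False)
    planted: Set[FeaturePair] = set()
    for i in range(config.n_planted):
        t1 = f"{TOKEN_PREFIX[kind]}{config.vocab_sizes[kind] + 2 * i:03d}"
        t2 = f"{TOKEN_PREFIX[kind]}{config.vocab_sizes[kind] + 2 * i + 1:03d}"
        block = chosen[2 * usage * i : 2 * usage * (i + 1)]
        for drug in block[:usage]:
            features[drug] = features[drug] | {t1}
        for drug in block[usage:]:
            features[drug] = features[drug] | {t2}
        planted.add(FeaturePair(kind, t1, t2))
    return planted


def _weighted_sample_without_replacement(
    rng: np.random.Generator, weights: np.ndarray, size: int
) -> np.ndarray:
    """Efraimidis-Spirakis keys: successive draws proportional to weight."""
    keys = rng.random(len(weights)) ** (1.0 / weights)
    return np.argsort(-keys, kind="stable")[:size]


def generate(config: SynthConfig) -> SyntheticDataset:
    """Generate annotations, combinations and planted truth from a seed."""
    rng = np.random.default_rng(config.seed)
    drugs = [f"D{i:03d}" for i in range(config.n_drugs)]
    all_pairs = [DrugPair(a, b) for a, b in iter_combinations(drugs, 2)]
    if config.n_combos > len(all_pairs):
        raise ValueError(
            f"n_combos={config.n_combos} exceeds the {len(all_pairs)} possible drug pairs"
        )

    annotations = DrugAnnotations()
    for drug in drugs:
        annotations.add_drug(drug)
    per_kind_features: Dict[FeatureKind, Dict[str, FrozenSet[str]]] = {}
    planted: Dict[FeatureKind, Set[FeaturePair]] = {}
    for kind in config.kinds:
        features = _assign_features(rng, drugs, kind, config)
        planted[kind] = _plant_tokens(rng, features, kind, config)
        per_kind_features[kind] = features
        for drug, tokens in features.items():
            annotations.add(drug, kind, tokens)

    planted_carriers: Dict[FeaturePair, Set[DrugPair]] = {}
    for kind in config.kinds:
        for pair in all_pairs:
            for fp in _pair_feature_pairs(per_kind_features[kind], kind, pair.a, pair.b):
                if fp in planted[kind]:
                    planted_carriers.setdefault(fp, set()).add(pair)

    n_planted_per_pair: Dict[DrugPair, int] = {}
    for fp, carriers in planted_carriers.items():
        for pair in carriers:
            n_planted_per_pair[pair] = n_planted_per_pair.get(pair, 0) + 1
    weights = np.array(
        [config.enrichment_strength ** min(n_planted_per_pair.get(p, 0), 4) for p in all_pairs]
    )

    n_noise = int(round(config.noise_frac * config.n_combos))
    n_signal = config.n_combos - n_noise
    signal_idx = _weighted_sample_without_replacement(rng, weights, n_signal)
    remaining = np.setdiff1d(np.arange(len(all_pairs)), signal_idx)
    noise_idx = rng.choice(remaining, size=n_noise, replace=False)
    combo_pairs = {all_pairs[i] for i in np.concatenate([signal_idx, noise_idx]).astype(int)}

    years: Dict[DrugPair, int] = {}
    if config.year_range is not None:
        start, end = config.year_range
        for pair in sorted(combo_pairs):
            years[pair] = int(rng.integers(start, end + 1))

    n_heldout = int(round(config.heldout_frac * config.n_combos))
    pool = sorted(combo_pairs)
    heldout = set()
    if n_heldout:
        idx = rng.choice(len(pool), size=n_heldout, replace=False)
        heldout = {pool[i] for i in idx}
    kept = combo_pairs - heldout
    combos = CombinationSet(kept, {p: y for p, y in years.items() if p in kept})

    sims = SimilarityTable(
        {pair: float(s) for pair, s in zip(all_pairs, rng.beta(2.0, 8.0, size=len(all_pairs)))}
    )
    return SyntheticDataset(annotations, combos, planted, heldout, sims, config)


def write_dataset(dataset: SyntheticDataset, out_dir, header=()) -> Dict[str, str]:
    """Write all input tables plus a provenance record; returns path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, str] = {}
    for kind in dataset.config.kinds:
        path = out / f"annotations_{kind.value}.tsv"
        dcio.write_annotations(dataset.annotations, kind, path, header)
        paths[f"annotations_{kind.value}"] = str(path)
    combo_path = out / "combinations.tsv"
    dcio.write_combinations(dataset.combos, combo_path, header)
    paths["combinations"] = str(combo_path)
    sim_path = out / "similarity.tsv"
    dcio.write_similarity(dataset.similarity, sim_path, header)
    paths["similarity"] = str(sim_path)

    provenance = {
        "seed": dataset.config.seed,
        "config": {
            k: (v if not isinstance(v, dict)
                else {getattr(kk, "value", kk): vv for kk, vv in v.items()})
            for k, v in dataclasses.asdict(dataset.config).items()
        },
        "planted": {
            kind.value: sorted([fp.f1, fp.f2] for fp in fps)
            for kind, fps in dataset.planted.items()
        },
        "heldout_positives": sorted([p.a, p.b] for p in dataset.heldout_positives),
    }
    prov_path = out / "provenance.json"
    prov_path.write_text(json.dumps(provenance, indent=2, default=str))
    paths["provenance"] = str(prov_path)
    return paths
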