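"""Core domain types: feature kinds, drug pairs, annotations, combination sets.

Drugs and feature tokens are opaque, case-sensitive strings. A *feature* is any
annotated property of a drug (a target protein, a third-level ATC code, an
indication, a pathway, a side effect); a *feature pair* is an unordered pair of
feature tokens, one contributed by each drug of a drug pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, FrozenSet, Iterable, Iterator, Mapping, Optional, Set, Tuple

logger = logging.getLogger(__name__)


class FeatureKind(str, Enum):
    """The six supported annotation kinds.

    ``main_target`` marks a drug's primary therapeutic target; at load time
    main targets are also unioned into ``target`` so that ``target`` is always
    the complete target set and ``main_target`` a subset used only for display
    emphasis (the ``d_m`` edge type in network exports).
    """

    TARGET = "target"
    MAIN_TARGET = "main_target"
    ATC3 = "atc3"
    INDICATION = "indication"
    PATHWAY = "pathway"
    SIDE_EFFECT = "side_effect"

    @classmethod
    def parse(cls, token: str) -> "FeatureKind":
        try:
            return cls(token)
        except ValueError:
            valid = ", ".join(k.value for k in cls)
            raise ValueError(f"unknown feature kind {token!r}; expected one of: {valid}") from None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The three kinds integrated by default for prediction (the most predictive
#: sources: therapy codes, targets, indication areas).
DEFAULT_KINDS: Tuple[FeatureKind, ...] = (
    FeatureKind.ATC3,
    FeatureKind.TARGET,
    FeatureKind.INDICATION,
)


@dataclass(frozen=True, order=True)
class DrugPair:
    """An unordered pair of distinct drugs, stored canonically with ``a < b``."""

    a: str
    b: str

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError(f"drug pair must consist of two distinct drugs, got {self.a!r} twice")
        if self.a > self.b:
            lo, hi = self.b, self.a
            object.__setattr__(self, "a", lo)
            object.__setattr__(self, "b", hi)

    def __iter__(self) -> Iterator[str]:
        return iter((self.a, self.b))

    def other(self, drug: str) -> str:
        if drug == self.a:
            return self.b
        if drug == self.b:
            return self.a
        raise KeyError(drug)


@dataclass(frozen=True, order=True)
class FeaturePair:
    """An unordered pair of feature tokens of one kind (``f1 <= f2``).

    ``f1 == f2`` is permitted: the two drugs of a pair may carry the same
    feature (e.g. a shared target protein).
    """

    kind: FeatureKind
    f1: str
    f2: str

    def __post_init__(self) -> None:
        if self.f1 > self.f2:
            lo, hi = self.f2, self.f1
            object.__setattr__(self, "f1", lo)
            object.__setattr__(self, "f2", hi)


class DrugAnnotations:
    """Per-drug feature-token sets, one set per :class:`FeatureKind`.

    Absence of a kind for a drug is distinct from an empty set: ``has(d, k)``
    reports whether the drug was annotated for the kind at all. Adding
    ``main_target`` tokens automatically unions them into ``target``.
    """

    def __init__(self) -> None:
        self.drugs: Set[str] = set()
        self._features: Dict[Tuple[str, FeatureKind], Set[str]] = {}

    def add(self, drug: str, kind: FeatureKind, tokens: Iterable[str]) -> None:
        kind = FeatureKind(kind)
        self.drugs.add(drug)
        self._features.setdefault((drug, kind), set()).update(tokens)
        if kind is FeatureKind.MAIN_TARGET:
            self._features.setdefault((drug, FeatureKind.TARGET), set()).update(
                self._features[(drug, kind)]
            )

    def add_drug(self, drug: str) -> None:
        self.drugs.add(drug)

    def get(self, drug: str, kind: FeatureKind) -> FrozenSet[str]:
        """Feature tokens of ``kind`` for ``drug``; empty if unannotated."""
        return frozenset(self._features.get((drug, FeatureKind(kind)), ()))

    def has(self, drug: str, kind: FeatureKind) -> bool:
        """Whether the drug carries an annotation record for the kind."""
        return (drug, FeatureKind(kind)) in self._features

    def kinds(self) -> Set[FeatureKind]:
        return {k for (_, k) in self._features}

    def merge(self, other: "DrugAnnotations") -> "DrugAnnotations":
        """Union another annotation table into this one (in place)."""
        self.drugs |= other.drugs
        for (drug, kind), tokens in other._features.items():
            self.add(drug, kind, tokens)
        return self

    def items(self, kind: FeatureKind) -> Iterator[Tuple[str, FrozenSet[str]]]:
        kind = FeatureKind(kind)
        for (drug, k), tokens in sorted(self._features.items()):
            if k is kind:
                yield drug, frozenset(tokens)

    def __contains__(self, drug: str) -> bool:
        return drug in self.drugs

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DrugAnnotations):
            return NotImplemented
        mine = {k: frozenset(v) for k, v in self._features.items()}
        theirs = {k: frozenset(v) for k, v in other._features.items()}
        return self.drugs == other.drugs and mine == theirs

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"DrugAnnotations({len(self.drugs)} drugs, {len(self._features)} records)"


@dataclass
class CombinationSet:
    """A set of known (approved) pairwise drug combinations, optionally dated."""

    pairs: Set[DrugPair] = field(default_factory=set)
    year: Dict[DrugPair, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pairs = set(self.pairs)
        self.year = {p: int(y) for p, y in self.year.items()}

    def drugs(self) -> Set[str]:
        return {d for p in self.pairs for d in p}

    def add(self, pair: DrugPair, year: Optional[int] = None) -> None:
        self.pairs.add(pair)
        if year is not None:
            self.year[pair] = int(year)

    def validate_against(self, annotations: DrugAnnotations) -> Set[str]:
        """Warn (not error) about combination drugs missing from annotations.

        Annotation coverage is incomplete in practice, so this is diagnostic.
        Returns the set of missing drugs.
        """
        missing = self.drugs() - annotations.drugs
        if missing:
            logger.warning(
                "%d combination drug(s) absent from annotations: %s",
                len(missing),
                ", ".join(sorted(missing)[:10]),
            )
        return missing

    def subset(self, pairs: Iterable[DrugPair]) -> "CombinationSet":
        pairs = set(pairs)
        return CombinationSet(pairs, {p: y for p, y in self.year.items() if p in pairs})

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[DrugPair]:
        return iter(sorted(self.pairs))

    def __contains__(self, pair: DrugPair) -> bool:
        return pair in self.pairs


@dataclass
class SimilarityTable:
    """Precomputed pairwise chemical similarities in [0, 1].

    Missing pairs mean *unknown* similarity, never zero.
    """

    entries: Dict[DrugPair, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pair, value in self.entries.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"similarity for {pair} out of [0, 1]: {value}")

    def get(self, pair: DrugPair) -> Optional[float]:
        return self.entries.get(pair)

    def __len__(self) -> int:
        return len(self.entries)
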