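"""Readers and writers for the plain tab-separated table dialect.

All tables are UTF-8 TSV without a header; lines starting with ``#`` are
comments (used for provenance headers) and blank lines are ignored.

* annotation table: ``drug_id <tab> feature_token``
* combination table: ``drug_a <tab> drug_b [<tab> year]``
* similarity table: ``drug_a <tab> drug_b <tab> similarity``
* network edge table: ``source <tab> target <tab> edge_property`` with
  properties ``dd`` (drug-drug combination), ``dp`` (drug-protein),
  ``d_m`` (drug-main-target), ``da`` (drug-therapy).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Iterator, List, Sequence, Tuple, Union

from .datamodel import (
    CombinationSet,
    DrugAnnotations,
    DrugPair,
    FeatureKind,
    SimilarityTable,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: Edge properties of the network-export dialect.
EDGE_PROPERTIES = ("dd", "dp", "d_m", "da")


class ParseError(ValueError):
    """A malformed line in an input table; carries the path and line number."""

    def __init__(self, path: PathLike, lineno: int, message: str) -> None:
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def _data_lines(path: PathLike) -> Iterator[Tuple[int, List[str]]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_annotations(path: PathLike, kind: FeatureKind) -> DrugAnnotations:
    """Read a two-column (drug, feature token) table for one feature kind."""
    kind = FeatureKind(kind)
    ann = DrugAnnotations()
    for lineno, fields in _data_lines(path):
        if len(fields) != 2:
            raise ParseError(path, lineno, f"expected 2 tab-separated columns, got {len(fields)}")
        drug, token = fields
        if not drug or not token:
            raise ParseError(path, lineno, "empty drug or feature token")
        ann.add(drug, kind, (token,))
    return ann


def write_annotations(ann: DrugAnnotations, kind: FeatureKind, path: PathLike,
                      header: Sequence[str] = ()) -> None:
    kind = FeatureKind(kind)
    with open(path, "w", encoding="utf-8") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for drug, tokens in ann.items(kind):
            for token in sorted(tokens):
                fh.write(f"{drug}\t{token}\n")


def merge_annotations(*tables: DrugAnnotations) -> DrugAnnotations:
    """Union annotation tables read from per-kind files into one."""
    merged = DrugAnnotations()
    for table in tables:
        merged.merge(table)
    return merged


def read_combinations(path: PathLike) -> CombinationSet:
    """Read a combination table; pairs are canonicalized and deduplicated."""
    combos = CombinationSet()
    for lineno, fields in _data_lines(path):
        if len(fields) not in (2, 3):
            raise ParseError(path, lineno, f"expected 2 or 3 columns, got {len(fields)}")
        a, b = fields[0], fields[1]
        if a == b:
            raise ParseError(path, lineno, f"self-pair {a!r} is not a valid combination")
        year = None
        if len(fields) == 3 and fields[2] != "":
            try:
                year = int(fields[2])
            except ValueError:
                raise ParseError(path, lineno, f"non-integer year {fields[2]!r}") from None
        pair = DrugPair(a, b)
        if pair in combos.pairs and year is not None and combos.year.get(pair) not in (None, year):
            logger.warning("%s:%d: duplicate pair %s-%s with conflicting year", path, lineno, a, b)
        combos.add(pair, year)
    return combos


def write_combinations(combos: CombinationSet, path: PathLike, header: Sequence[str] = ()) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for pair in sorted(combos.pairs):
            year = combos.year.get(pair)
            if year is None:
                fh.write(f"{pair.a}\t{pair.b}\n")
            else:
                fh.write(f"{pair.a}\t{pair.b}\t{year}\n")


def read_similarity(path: PathLike) -> SimilarityTable:
    entries = {}
    for lineno, fields in _data_lines(path):
        if len(fields) != 3:
            raise ParseError(path, lineno, f"expected 3 columns, got {len(fields)}")
        a, b, raw = fields
        try:
            value = float(raw)
        except ValueError:
            raise ParseError(path, lineno, f"non-numeric similarity {raw!r}") from None
        if not 0.0 <= value <= 1.0:
            raise ParseError(path, lineno, f"similarity {value} out of [0, 1]")
        entries[DrugPair(a, b)] = value
    return SimilarityTable(entries)


def write_similarity(sims: SimilarityTable, path: PathLike, header: Sequence[str] = ()) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for pair in sorted(sims.entries):
            fh.write(f"{pair.a}\t{pair.b}\t{sims.entries[pair]:.6g}\n")


Edge = Tuple[str, str, str]


def write_network_edges(edges: Iterable[Edge], path: PathLike, header: Sequence[str] = ()) -> None:
    """Write a three-column edge table in the dd/dp/d_m/da dialect.

    Lines are emitted in deterministic lexicographic order.
    """
    rows = []
    for source, target, prop in edges:
        if prop not in EDGE_PROPERTIES:
            raise ValueError(
                f"unknown edge property {prop!r}; expected one of {EDGE_PROPERTIES}"
            )
        rows.append((source, target, prop))
    with open(path, "w", encoding="utf-8") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for source, target, prop in sorted(rows):
            fh.write(f"{source}\t{target}\t{prop}\n")


def read_network_edges(path: PathLike) -> List[Edge]:
    edges: List[Edge] = []
    for lineno, fields in _data_lines(path):
        if len(fields) != 3:
            raise ParseError(path, lineno, f"expected 3 columns, got {len(fields)}")
        source, target, prop = fields
        if prop not in EDGE_PROPERTIES:
            raise ParseError(path, lineno, f"unknown edge property {prop!r}")
        edges.append((source, target, prop))
    return edges
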