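from __future__ import annotations

import numpy as np
import pytest

from drugcombo.datamodel import (
    CombinationSet,
    DrugAnnotations,
    DrugPair,
    FeatureKind,
)


@pytest.fixture
def toy_annotations() -> DrugAnnotations:
    """Two drugs with target sets {p1,p2} and {p3,p4,p5}, plus a third drug."""
    ann = DrugAnnotations()
    ann.add("d1", FeatureKind.TARGET, {"p1", "p2"})
    ann.add("d2", FeatureKind.TARGET, {"p3", "p4", "p5"})
    ann.add("d3", FeatureKind.TARGET, {"p1"})
    ann.add("d1", FeatureKind.ATC3, {"A01"})
    ann.add("d2", FeatureKind.ATC3, {"A02"})
    return ann


def random_instance(seed: int, n_drugs: int = 10, n_combos: int = 6,
                    n_tokens: int = 6, max_features: int = 3, kinds=(FeatureKind.TARGET,)):
    """A small random annotations + combinations instance for oracle tests.

    Independent of the synthetic module: plain uniform draws, no planted
    structure, occasionally empty feature sets.
    """
    rng = np.random.default_rng(seed)
    drugs = [f"d{i:02d}" for i in range(n_drugs)]
    ann = DrugAnnotations()
    for drug in drugs:
        ann.add_drug(drug)
        for kind in kinds:
            k = int(rng.integers(0, max_features + 1))
            if k == 0 and rng.random() < 0.5:
                continue  # absent kind, distinct from empty
            tokens = rng.choice(n_tokens, size=k, replace=False) if k else []
            ann.add(drug, kind, {f"t{int(t)}" for t in tokens})
    all_pairs = [
        DrugPair(drugs[i], drugs[j])
        for i in range(n_drugs) for j in range(i + 1, n_drugs)
    ]
    idx = rng.choice(len(all_pairs), size=min(n_combos, len(all_pairs)), replace=False)
    combos = CombinationSet({all_pairs[i] for i in idx})
    return ann, combos


@pytest.fixture(scope="session")
def synthetic_default():
    """One default-condition synthetic dataset, shared across tests."""
    from drugcombo.synthetic import SynthConfig, generate

    return generate(SynthConfig(seed=20260920))
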