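from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from drugcombo.datamodel import (
    CombinationSet,
    DrugAnnotations,
    DrugPair,
    FeatureKind,
    FeaturePair,
    SimilarityTable,
)
from drugcombo.featurepairs import build_background, build_enrichment_table
from drugcombo.netanalysis import (
    CoCombinedPair,
    build_drug_feature_network,
    co_combined_pairs,
    feature_correlation,
    novelty_timeline,
    shared_feature_enrichment,
    similarity_check,
)

from conftest import random_instance
from _oracles import brute_co_combined, brute_fisher_two_sided

T = FeatureKind.TARGET


class TestCoCombined:
    def test_single_witness(self):
        combos = CombinationSet({DrugPair("A", "C"), DrugPair("B", "C")})
        found = co_combined_pairs(combos)
        assert found == {CoCombinedPair(DrugPair("A", "B"), frozenset({"C"}), False)}

    def test_single_combo_gives_none(self):
        combos = CombinationSet({DrugPair("A", "B")})
        assert co_combined_pairs(combos) == set()

    def test_star_gives_all_leaf_pairs(self):
        combos = CombinationSet({DrugPair(x, "Z") for x in ("A", "B", "C")})
        found = co_combined_pairs(combos)
        assert {c.pair for c in found} == {
            DrugPair("A", "B"), DrugPair("A", "C"), DrugPair("B", "C")
        }

    def test_approved_pair_flagged(self):
        combos = CombinationSet(
            {DrugPair("A", "C"), DrugPair("B", "C"), DrugPair("A", "B")}
        )
        flagged = {c.pair: c.is_combination for c in co_combined_pairs(combos)}
        assert flagged[DrugPair("A", "B")] is True

    def test_matches_brute_force(self):
        for seed in range(25):
            _, combos = random_instance(seed, n_drugs=15, n_combos=12)
            expected = brute_co_combined(combos)
            found = co_combined_pairs(combos)
            assert {c.pair: set(c.witnesses) for c in found} == expected


class TestSharedFeatureEnrichment:
    def test_perfect_association(self):
        """a=5,b=0,c=0,d=5 has two-sided exact p = 2/C(10,5)."""
        ann = DrugAnnotations()
        co, other = [], []
        for i in range(5):
            x, y = f"s{i}x", f"s{i}y"
            ann.add(x, T, {f"shared{i}"})
            ann.add(y, T, {f"shared{i}"})
            co.append(CoCombinedPair(DrugPair(x, y), frozenset({"w"}), False))
            u, v = f"u{i}x", f"u{i}y"
            ann.add(u, T, {f"left{i}"})
            ann.add(v, T, {f"right{i}"})
            other.append(DrugPair(u, v))
        all_pairs = [c.pair for c in co] + other
        res = shared_feature_enrichment(co, all_pairs, ann, T)
        assert res.table == ((5, 0), (0, 5))
        assert res.p_value == pytest.approx(2 / 252, rel=1e-9)
        assert res.p_value == pytest.approx(brute_fisher_two_sided(5, 0, 0, 5), rel=1e-9)

    def test_no_association(self):
        ann = DrugAnnotations()
        co, other = [], []
        for i in range(4):
            shared = i % 2 == 0
            x, y = f"c{i}x", f"c{i}y"
            ann.add(x, T, {"t"} if shared else {f"a{i}"})
            ann.add(y, T, {"t"} if shared else {f"b{i}"})
            co.append(CoCombinedPair(DrugPair(x, y), frozenset({"w"}), False))
            u, v = f"o{i}x", f"o{i}y"
            ann.add(u, T, {"t"} if shared else {f"e{i}"})
            ann.add(v, T, {"t"} if shared else {f"f{i}"})
            other.append(DrugPair(u, v))
        res = shared_feature_enrichment(co, [c.pair for c in co] + other, ann, T)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value >= 0.99

    def test_zero_shared_cocombined_gives_zero_odds(self):
        ann = DrugAnnotations()
        ann.add("a", T, {"p"})
        ann.add("b", T, {"q"})
        ann.add("c", T, {"r"})
        ann.add("d", T, {"r"})
        co = [CoCombinedPair(DrugPair("a", "b"), frozenset({"w"}), False)]
        res = shared_feature_enrichment(co, [DrugPair("a", "b"), DrugPair("c", "d")], ann, T)
        assert res.odds_ratio == 0.0

    def test_degenerate_margin_errors(self):
        ann = DrugAnnotations()
        ann.add("a", T, {"p"})
        ann.add("b", T, {"p"})
        co = [CoCombinedPair(DrugPair("a", "b"), frozenset({"w"}), False)]
        with pytest.raises(ValueError, match="degenerate"):
            shared_feature_enrichment(co, [DrugPair("a", "b")], ann, T)

    @pytest.mark.parametrize("seed", range(20))
    def test_p_value_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = (int(x) for x in rng.integers(0, 8, size=4) + [1, 0, 0, 1])
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        assert p == pytest.approx(brute_fisher_two_sided(a, b, c, d), rel=1e-7)


class TestNoveltyTimeline:
    @staticmethod
    def _ann(pairs):
        ann = DrugAnnotations()
        for drug, targets in pairs.items():
            ann.add(drug, T, targets)
        return ann

    def test_repeat_of_earlier_target_pair(self):
        ann = self._ann({"a": {"p"}, "b": {"q"}, "c": {"p"}, "d": {"q"}})
        combos = CombinationSet(
            {DrugPair("a", "b"), DrugPair("c", "d")},
            {DrugPair("a", "b"): 1990, DrugPair("c", "d"): 2000},
        )
        frame = novelty_timeline(combos, ann, baseline_year=1985)
        by_year = frame.set_index("year")
        assert by_year.loc[1990, "n_novel"] == 1
        assert by_year.loc[2000, "n_repeat"] == 1

    def test_first_post_baseline_with_new_targets_is_novel(self):
        ann = self._ann({"a": {"p"}, "b": {"q"}, "c": {"r"}, "d": {"s"}})
        combos = CombinationSet(
            {DrugPair("a", "b"), DrugPair("c", "d")},
            {DrugPair("a", "b"): 1980, DrugPair("c", "d"): 1990},
        )
        frame = novelty_timeline(combos, ann, baseline_year=1983)
        assert frame.loc[frame["year"] == 1990, "n_novel"].item() == 1
        assert 1980 not in set(frame["year"])  # baseline rows are not counted

    def test_same_year_ties_compared_to_strictly_earlier_only(self):
        """Two same-year combos sharing a target pair are both novel if the
        pattern was never seen before that year."""
        ann = self._ann({"a": {"p"}, "b": {"q"}, "c": {"p"}, "d": {"q"},
                         "e": {"x"}, "f": {"y"}})
        combos = CombinationSet(
            {DrugPair("a", "b"), DrugPair("c", "d"), DrugPair("e", "f")},
            {DrugPair("a", "b"): 1995, DrugPair("c", "d"): 1995,
             DrugPair("e", "f"): 1990},
        )
        frame = novelty_timeline(combos, ann, baseline_year=1985)
        row = frame.set_index("year").loc[1995]
        assert row["n_novel"] == 2 and row["n_repeat"] == 0

    def test_missing_year_skipped(self, caplog):
        ann = self._ann({"a": {"p"}, "b": {"q"}, "c": {"p"}, "d": {"q"}})
        combos = CombinationSet(
            {DrugPair("a", "b"), DrugPair("c", "d")},
            {DrugPair("a", "b"): 1990},
        )
        frame = novelty_timeline(combos, ann, baseline_year=1980)
        assert frame["n_repeat"].sum() + frame["n_novel"].sum() == 1

    def test_cumulative_fractions(self):
        ann = self._ann({"a": {"p"}, "b": {"q"}, "c": {"p"}, "d": {"q"}})
        combos = CombinationSet(
            {DrugPair("a", "b"), DrugPair("c", "d")},
            {DrugPair("a", "b"): 1990, DrugPair("c", "d"): 2000},
        )
        frame = novelty_timeline(combos, ann, baseline_year=1985)
        assert frame["cum_frac_repeat"].iloc[-1] == pytest.approx(0.5)


class TestSimilarityCheck:
    def _co(self, pairs):
        return [CoCombinedPair(p, frozenset({"w"}), False) for p in pairs]

    def test_all_zero(self):
        pairs = [DrugPair("a", "b"), DrugPair("c", "d")]
        sims = SimilarityTable({p: 0.0 for p in pairs})
        assert similarity_check(self._co(pairs), sims) == (2, 0, 0)

    def test_cutoff_is_strict(self):
        pairs = [DrugPair("a", "b")]
        sims = SimilarityTable({pairs[0]: 0.6})
        assert similarity_check(self._co(pairs), sims, cutoff=0.6) == (1, 0, 0)

    def test_counts_above(self):
        pairs = [DrugPair("a", "b"), DrugPair("c", "d"), DrugPair("e", "f")]
        sims = SimilarityTable(dict(zip(pairs, [0.5, 0.7, 0.9])))
        assert similarity_check(self._co(pairs), sims, cutoff=0.6) == (3, 2, 0)

    def test_unknown_reported_separately(self):
        pairs = [DrugPair("a", "b"), DrugPair("c", "d")]
        sims = SimilarityTable({pairs[0]: 0.8})
        assert similarity_check(self._co(pairs), sims) == (2, 1, 1)


class TestFeatureCorrelation:
    def test_self_correlation_is_one(self, synthetic_default):
        ds = synthetic_default
        tables = {
            k: build_enrichment_table(ds.combos, ds.annotations, k)
            for k in (T, FeatureKind.ATC3)
        }
        corr = feature_correlation(ds.combos, ds.annotations, tables)
        assert corr.loc["target", "target"] == 1.0
        assert corr.loc["atc3", "atc3"] == 1.0
        assert corr.equals(corr.T)

    def test_anti_monotone_scores_give_minus_one(self):
        """Per-combination best scores in strictly opposite rank order."""
        from drugcombo.featurepairs import EnrichmentEntry, EnrichmentTable

        ann = DrugAnnotations()
        combos = CombinationSet()
        t_entries, a_entries = {}, {}
        for i in range(6):
            a, b = f"a{i}", f"b{i}"
            ann.add(a, T, {f"x{i}"})
            ann.add(b, T, {f"y{i}"})
            ann.add(a, FeatureKind.ATC3, {f"u{i}"})
            ann.add(b, FeatureKind.ATC3, {f"v{i}"})
            combos.add(DrugPair(a, b))
            t_entries[FeaturePair(T, f"x{i}", f"y{i}")] = EnrichmentEntry(1, 1, float(i))
            a_entries[FeaturePair(FeatureKind.ATC3, f"u{i}", f"v{i}")] = EnrichmentEntry(
                1, 1, float(-i)
            )
        tables = {
            T: EnrichmentTable(T, t_entries, 6, 6),
            FeatureKind.ATC3: EnrichmentTable(FeatureKind.ATC3, a_entries, 6, 6),
        }
        corr = feature_correlation(combos, ann, tables)
        assert corr.loc["target", "atc3"] == pytest.approx(-1.0)

    def test_independent_kinds_near_zero(self):
        rng = np.random.default_rng(0)
        ann = DrugAnnotations()
        combos = CombinationSet()
        for i in range(40):
            a, b = f"a{i:02d}", f"b{i:02d}"
            ann.add(a, T, {f"t{int(rng.integers(8))}"})
            ann.add(b, T, {f"t{int(rng.integers(8))}"})
            ann.add(a, FeatureKind.ATC3, {f"c{int(rng.integers(8))}"})
            ann.add(b, FeatureKind.ATC3, {f"c{int(rng.integers(8))}"})
            combos.add(DrugPair(a, b))
        tables = {
            k: build_enrichment_table(combos, ann, k) for k in (T, FeatureKind.ATC3)
        }
        corr = feature_correlation(combos, ann, tables)
        assert abs(corr.loc["target", "atc3"]) < 0.45

    def test_single_kind_rejected(self, synthetic_default):
        ds = synthetic_default
        tables = {T: build_enrichment_table(ds.combos, ds.annotations, T)}
        with pytest.raises(ValueError):
            feature_correlation(ds.combos, ds.annotations, tables)


class TestDrugFeatureNetwork:
    def test_basic_construction(self):
        ann = DrugAnnotations()
        ann.add("A", T, {"p"})
        ann.add("B", T, {"q"})
        combos = CombinationSet({DrugPair("A", "B")})
        table = build_enrichment_table(combos, ann, T)
        edges = build_drug_feature_network(combos, ann, T, table, threshold=-10.0)
        assert set(edges) == {("A", "B", "dd"), ("A", "p", "dp"), ("B", "q", "dp")}

    def test_main_target_marked(self):
        ann = DrugAnnotations()
        ann.add("A", FeatureKind.MAIN_TARGET, {"p"})
        ann.add("B", T, {"q"})
        combos = CombinationSet({DrugPair("A", "B")})
        table = build_enrichment_table(combos, ann, T)
        edges = build_drug_feature_network(combos, ann, T, table, threshold=-10.0)
        assert ("A", "p", "d_m") in edges
        assert ("B", "q", "dp") in edges

    def test_therapy_kind_uses_da(self):
        ann = DrugAnnotations()
        ann.add("A", FeatureKind.ATC3, {"C10A"})
        ann.add("B", FeatureKind.ATC3, {"C04A"})
        combos = CombinationSet({DrugPair("A", "B")})
        table = build_enrichment_table(combos, ann, FeatureKind.ATC3)
        edges = build_drug_feature_network(combos, ann, FeatureKind.ATC3, table, -10.0)
        assert ("A", "C10A", "da") in edges and ("B", "C04A", "da") in edges

    def test_threshold_filters_combinations(self, synthetic_default):
        ds = synthetic_default
        table = build_enrichment_table(ds.combos, ds.annotations, T)
        all_edges = build_drug_feature_network(ds.combos, ds.annotations, T, table, -100.0)
        strict = build_drug_feature_network(ds.combos, ds.annotations, T, table, 2.0)
        assert set(strict) <= set(all_edges)
        dd_strict = [e for e in strict if e[2] == "dd"]
        dd_all = [e for e in all_edges if e[2] == "dd"]
        assert len(dd_strict) < len(dd_all)

    def test_empty_combos_empty_edges(self):
        from drugcombo.featurepairs import EnrichmentTable

        ann = DrugAnnotations()
        ann.add("A", T, {"p"})
        edges = build_drug_feature_network(
            CombinationSet(), ann, T, EnrichmentTable(T), -10.0
        )
        assert edges == []
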