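"""Descriptive analyses: co-combination structure, networks, history.

Builds the drug-feature network export, tests whether co-combined drugs (two
drugs approved with a common third partner) share targets more often than
other drug pairs, checks their chemical similarity, and classifies each
year's combinations as re-using earlier target pairs or targeting novel ones.
"""

from drugcombo import FeatureKind, build_background, build_enrichment_table
from drugcombo.netanalysis import (
    build_drug_feature_network,
    co_combined_pairs,
    novelty_timeline,
    shared_feature_enrichment,
    similarity_check,
)
from drugcombo.synthetic import SynthConfig, generate

dataset = generate(SynthConfig(seed=1, year_range=(1984, 2010)))
kind = FeatureKind.TARGET

table = build_enrichment_table(dataset.combos, dataset.annotations, kind)
edges = build_drug_feature_network(dataset.combos, dataset.annotations, kind, table, 1.0)
print(f"drug-protein network: {len(edges)} edges "
      f"({sum(1 for e in edges if e[2] == 'dd')} combination edges)")

cocombined = co_combined_pairs(dataset.combos)
universe = build_background(dataset.combos)
shared = shared_feature_enrichment(cocombined, universe, dataset.annotations, kind)
n_co = shared.n_shared_cocombined + shared.n_unshared_cocombined
print(f"\nco-combined pairs: {n_co}; sharing a target: {shared.n_shared_cocombined}")
print(f"odds ratio {shared.odds_ratio:.2f}, two-sided exact p = {shared.p_value:.3g}")

n_total, n_above, n_unknown = similarity_check(cocombined, dataset.similarity, 0.6)
print(f"chemically similar (>0.6) co-combined pairs: {n_above}/{n_total}")

timeline = novelty_timeline(dataset.combos, dataset.annotations, baseline_year=1988)
frac = timeline["cum_frac_repeat"].iloc[-1]
print(f"\ncombinations re-using earlier target pairs: {frac:.0%} "
      f"(over {int(timeline['n_repeat'].sum() + timeline['n_novel'].sum())} dated combos)")

# A large odds ratio with a small exact p-value says interchangeable partners
# share pharmacology (targets) rather than chemistry (the similarity check),
# and the timeline shows how often new approvals revisit known target pairs.
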