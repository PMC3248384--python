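# Methods

`drugcombo` predicts pairwise drug combinations from the molecular and
pharmacological features of the individual drugs, and provides the
descriptive analyses that motivate the model. This note records the model,
its assumptions, the tunable parameters, the synthetic test bed, and the
numerical choices a maintainer would want to know about.

## Model

### Feature-pair representation

Each drug carries, per feature kind *k* (target proteins, third-level ATC
therapy codes, indication areas, pathways, side effects), a set of opaque
feature tokens. A drug pair (d₁, d₂) is represented, per kind, by the set of
unordered *feature pairs* {(f, g) : f ∈ F_k(d₁), g ∈ F_k(d₂)} — the Cartesian
product of the two drugs' token sets, canonicalized so (f, g) = (g, f).
Self-pairs (f, f) are allowed: two combined drugs may share a target.

### Enrichment score

Feature pairs are scored by comparing their frequency among approved
combinations with their frequency in the *background set* — all unordered
pairs of drugs that appear in at least one approved combination:

    score(f, g) = log2( ((n_comb + c) / (N_comb + c)) /
                        ((n_bg   + c) / (N_bg   + c)) )

where `n_comb` / `n_bg` count the drug pairs (combinations / background)
whose representation contains (f, g); `N_comb` / `N_bg` count drug pairs
contributing at least one feature pair of the kind; and `c > 0` is a
pseudocount (default 1.0). Counting is per drug pair (presence, not
multiplicity): the drug pair is the sampling unit. Normalization is by drug
pairs contributing at least one feature pair, not by feature-pair tokens.

Every downstream quantity depends only on the *rank order* of these scores
(the precision calibration below is rank-based), so any strictly monotone
variant of the frequency ratio yields identical predictions; this is verified
by a rank-invariance test. Two consequences of the pseudocount are worth
knowing: a feature pair absent from combinations does not necessarily score
below zero when the background totals dwarf the combination totals, and all
low-count pairs are shifted upward by roughly log2((N_bg + c)/(N_comb + c)) —
a pair observed once in the background and once in a combination attains the
maximal possible ratio. Tie-breaking in rankings is lexicographic on the
canonical token pair, for reproducibility.

### Precision calibration and noisy-OR integration

Raw enrichment scores from different sources are not commensurable. Each
source is therefore calibrated on the training set: every background drug
pair is represented by its best (maximum) feature-pair score, and for each
distinct best score *s* the curve stores

    precision(s) = |{pairs with best score >= s} ∩ training combinations|
                   / |{pairs with best score >= s}|.

The threshold comparison is inclusive (>=): a strict inequality would leave
the top-ranked feature pair with an empty, undefined prediction set. The
confidence source *k* lends a drug pair is the maximum precision attained at
the score of any of its feature pairs; a pair with no information from source
*k* (no features, or only feature pairs unseen in training) contributes 0 —
unseen pairs are handled conservatively rather than interpolated. Scores
above every training threshold also return 0 (no training support); this
cannot occur when scoring with the table that built the curve.

Per-source confidences are aggregated noisy-OR style:

    P(d₁, d₂) = 1 − Π_k (1 − P_k(d₁, d₂)).

This integration is monotone in every argument, bounded by
max_k P_k <= P <= Σ_k P_k, absorbing at 1, and treats sources as independent
lines of evidence — the design intent being that sources with complementary
coverage rescue each other's gaps rather than requiring consensus. The
default integrated kinds are ATC level-3 therapy codes, targets and
indications, the three most informative sources.

### Cross-validation and threshold selection

Only the positives are folded: approved combinations are split into 5
near-equal folds (sizes differ by at most one; 184 positives give
{37,37,37,37,36}). There are no verified negative examples, so every
background pair that is never a positive serves as a negative in every fold;
reported performance is therefore conservative. For each fold, enrichment
tables and precision curves are fit on the training folds only (fold-local
calibration — no validation pair influences its own score), and the held-out
positives plus all negatives are scored. The procedure is repeated (default
10 times) and averaged: ROC curves vertically at a fixed 101-point
false-positive-rate grid, the F1-versus-threshold curve at a fixed grid of
all distinct observed combined scores plus {0, 1} (so the F1 optimum is exact,
with no arbitrary binning). The operating threshold is the maximizer of mean
F1, ties resolved toward the larger threshold (fewer predictions). Folds in
which no validation positive carries a given kind's features are skipped in
that kind's single-source ROC, with a warning.

### Candidate screening

The candidate universe is every unordered pair of drugs involved in some
known combination, minus the known combinations themselves and minus pairs
touching a user-supplied exclusion list (drug classes whose combination
space is already saturated are excluded by curation, not hard-coded). The
model is trained on all positives; candidates at or above the threshold are
emitted in descending confidence order, each carrying per-source confidences
(also below-threshold ones, for transparency) and the argmax feature pair(s)
per source as the mechanistic rationale.

### Descriptive analyses

* **Drug-feature networks.** For each combination whose best feature-pair
  score of a kind reaches a threshold: a `dd` (drug-drug) edge, plus edges
  from each drug to its feature(s) in the best-scoring pattern(s) — `dp` for
  proteins/pathways, `da` for therapy and indication codes, `d_m` when the
  feature is among the drug's annotated main targets. Ties at the best score
  all contribute. Exports are three-column TSV, lexicographically sorted.
* **Co-combined pairs.** Two drugs each approved in combination with a common
  third drug. The shared-feature test builds a 2×2 table (co-combined vs all
  other unordered pairs of background drugs) × (sharing >= 1 feature token vs
  not) and reports the odds ratio and a two-sided exact p-value (sum of
  hypergeometric tables with probability <= the observed one, the standard
  convention). The complement stratum — all background pairs that are not
  co-combined — is one reasonable choice among several; it is a package
  decision, not a canonical definition. Pairs that are themselves approved
  combinations are retained and flagged.
* **Similarity check.** Counts co-combined pairs with known chemical
  similarity strictly greater than a cutoff (default 0.6); unknown
  similarities are reported separately, never treated as zero.
* **Target-pair novelty timeline.** Combinations with approval years are
  processed in year order; one is a *repeat* if any of its target pairs was
  targeted by a strictly earlier combination (or by the baseline set, all
  combinations up to the baseline year), else *novel*. Same-year combinations
  are classified together against the strictly-earlier set only, so the
  result is order-invariant within a year. Undated or target-less
  combinations are skipped.
* **Feature correlations.** Per kind, each combination is represented by its
  best feature-pair score; Spearman rank correlations are computed pairwise
  over combinations with information in both kinds (fewer than 3 common
  observations gives NaN).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `pseudocount` | 1.0 | additive smoothing in the enrichment ratio; guarantees finite scores for background-only pairs |
| `kinds` | atc3, target, indication | sources entering the noisy-OR integration |
| `n_folds` / `n_repeats` | 5 / 10 | cross-validation protocol |
| `threshold` | 0.4 | default screening threshold of the `predict` CLI; in practice re-derived per dataset from the F1 curve |
| similarity cutoff | 0.6 | "chemically similar" in the co-combination check |

## Synthetic data generator

The generator emulates the statistical structure the method assumes: a
minority of feature pairs strongly over-represented among true combinations,
embedded in a noisy background, with incomplete per-source annotation
coverage. Defaults (one dataset = one draw of the default `SynthConfig`):

* 60 drugs; 184 combinations (so a 5-fold split reproduces validation folds
  of about 37); three kinds — targets (vocabulary 20, 2–4 tokens per drug),
  ATC level-3 codes (12, 1–2), indications (14, 2–3); per-kind coverage 0.75
  (a quarter of drugs lack each source, independently per kind, which is what
  makes integration genuinely useful); noise fraction 0.1; 10% of positives
  withheld as a recovery test set.
* Token popularity is skewed (Zipf-like extras over a per-token usage floor
  of 4 carrier drugs), so common features create realistic background noise
  while no regular feature pair is a near-singleton. The floor matters: under
  a pseudocounted ratio score, a feature pair with one background carrier
  that happens to be a combination attains the maximal possible score, so a
  generator full of singleton pairs would bury any planted signal — a
  property of this score family, not an implementation artifact.
* Planted signal: per kind, 5 feature pairs built from dedicated fresh
  tokens, each token carried by 3 drugs, with carrier drug sets disjoint
  within a kind. Disjointness prevents "hitchhiker" cross-pairs of planted
  tokens from inheriting the enrichment; the small carrier sets (9 background
  pairs per planted pair) keep the total planted mass coverable by the
  sampled combinations. Combinations are then drawn without replacement with
  probability proportional to `enrichment_strength ^ (number of planted pairs
  contained)` (default strength 50), plus the uniform noise fraction.

What the generator does **not** emulate: real ontology structure (ATC
hierarchy, MeSH trees), correlated sources (targets inducing pathways),
dosage/formulation duplicates, any chemistry (similarities are independent
Beta(2, 8) draws), or the extreme sparsity of real corpora (184 positives
among 1,770 candidate pairs is ~10%, versus well under 1% in curated data).
Passing tests on this bed demonstrate that the statistical machinery recovers
planted enrichment structure and that integration of partially-covering
sources helps; they say nothing about the biological validity of predictions
on real annotations.

Under the default conditions, all 15 planted pairs rank in their kind's top
10 in ≈98 of 100 seeds, withheld positives sit at a median rank percentile of
≈2% among negatives, and the integrated AUROC (≈0.75–0.8) exceeds every
single source (≈0.55–0.65). Planted-rank recovery is measured on datasets
generated without the withheld subset, since withholding positives only
depresses the planted counts and is orthogonal to what that check measures.
Recovery degrades gracefully with `enrichment_strength`: near the bottom of
the spec'd regime (≈20) the sampled combinations cover too small a fraction
of the planted carrier pairs for all five pairs to stay in the top 10.

## Numerical choices and degenerate inputs

* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; repeated runs are byte-identical.
* Drug pairs and feature pairs are stored canonically (lexicographically
  ordered components); all output files are written in sorted order.
* Weighted sampling without replacement uses Efraimidis–Spirakis keys
  (u^(1/w)), equivalent to sequential draws proportional to weight.
* An enrichment table for a kind absent from all combinations still assigns
  the pseudocounted score (every pair is background-only); the precision
  curve then yields confidence 0 throughout, so such a source is inert.
* `precision_at` on an empty curve, or a score above all thresholds, is 0.
* Degenerate 2×2 tables (an empty margin) raise an error rather than
  returning a meaningless p-value.
* F1 is defined as 0 when precision + recall = 0; precision of an empty
  prediction set is 0.

## Limitations

* The method can only propose combinations resembling existing ones: it
  ranks feature pairs by enrichment among approved combinations, so genuinely
  novel mechanism pairs score low by construction.
* Negatives are unverified (absence of approval is not evidence of
  ineffectiveness); all performance numbers are lower bounds in that sense.
* The precision calibration is a step function of training best-scores;
  confidences for sparse sources are coarse.
* The exact algebraic form of the enrichment score is a package decision
  (log2 pseudocounted frequency ratio matching the verbal definition);
  alternatives differ only through ties, since downstream quantities are
  rank-based.
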