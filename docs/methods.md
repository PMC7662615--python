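# Methods

## Loss indexing and discretization

The binaural loss index is computed in two stages. Per ear, the monaural
loss percentage is `(mean of the 500/1000/2000/3000 Hz thresholds − 25 dB)
× 1.5`. The 25 dB term is the low fence below which no social handicap is
counted; 1.5 converts decibels above the fence into percentage points. The
binaural index is the 5:1 weighted mean of the better (smaller-loss) and
worse ear, `(5·better + worse)/6`, which is symmetric in the ears and
always lies between the two monaural values — when the monaural losses tie
the formula is invariant to which ear is called "better", so no tie rule is
needed.

**Clamping.** We clamp the monaural percentage to [0, 100] at both ends.
The floor is forced by the index's definition as a percentage and by
cohort minima sitting at exactly 0 %; the cap mirrors the standard
social-hearing-loss method. Whether a particular study truncated at the
top is usually unreported; the cap only matters above 91.7 dB HL mean
threshold, far outside the occupational range.

**Interval conventions.** The loss-group bins are lower-exclusive /
upper-inclusive — group 1 is exactly 0 %, group 2 is (0, 15], and so on —
while the age quintiles are lower-inclusive / upper-exclusive ([17, 29),
[29, 35), …, [49, ∞)). The two discretizers deliberately use opposite
edge conventions because that is how such tables are conventionally
printed; both are covered by partition property tests over dense grids.
Internally loss groups are the strings "1"–"5"; Roman numerals and
"Group k" notation are accepted on input and Roman numerals are written to
CSV, since both notations denote the same five states in published tables.
Percentages are kept at full precision internally and rounded half-even to
2 decimals only at the presentation layer.

## The Bayesian network

The joint over gender (2 states), age group (5), family history (2) and
loss group (5) is factorized as p(x₁,…,x₄) = ∏ p(xᵢ | πᵢ) over a DAG. The
canonical topology — the three predictors parentless, each a parent of the
loss group — has 1 + 4 + 1 + 4·(2·5·2) = 86 free parameters (the
unrestricted joint needs 2·5·2·5 − 1 = 99) and reproduces every
conditional P(loss group | predictor subset) that published sensitivity
tables report.

**Parameter fitting.** CPT entries are `(count + α) / (row total +
α·card)`. α = 0 (pure maximum likelihood) is the default for headline
fits; an unobserved parent configuration then falls back to a uniform row,
which is the only unbiased-by-construction choice when nothing was seen.
α = 1 is the default inside cross-validation so held-out configurations
never receive a hard zero score — the loss-group variable has 5 states and
its rarest state has cohort frequency of order 1/1000, so sparse folds are
the norm, not the exception.

**Inference.** Posteriors are exact, by sum–product variable elimination
with a min-degree elimination order (the order affects speed only, not
exactness, and these networks are tiny). Evidence with zero marginal
probability raises an explicit `ImpossibleEvidenceError` rather than
returning NaNs. All factor arithmetic is in linear space; only the BIC
log-likelihood works in logs. Equality with brute-force joint enumeration
to 1e-12 is enforced by a seeded property suite over random networks with
up to 6 variables and 5 states.

**Structure learning.** Greedy hill climbing over add/delete/reverse
single-edge moves, scored by BIC (log-likelihood at the MLE minus
(k/2)·ln N), which decomposes over families; candidate moves are
enumerated in lexicographic (child, parent) order so ties break
deterministically, and seeded random restarts perturb the start graph.
The search is validated against exhaustive enumeration of all DAGs on
three study variables: it attains the global BIC optimum.

**A deliberate caveat on structure recovery at cohort scale.** The
family-history effect in the generating tables is worth roughly 8 nats of
log-likelihood at n = 50,000 (n·MI ≈ 8), below the ≈ 22-nat BIC penalty of
the cheapest edge that could carry it, and population-level scoring of all
543 four-node DAGs shows the three-predictor collider only becomes the
global BIC optimum near n ≈ 10⁷. BIC is consistent, but at realistic
cohort sizes it prefers a sparser graph for effects this weak; the
equivalence-class recovery test therefore uses a strong-signal noisy-XOR
collider, while on study-scale data we test that the climber finds the
global optimum of its score, not that the score identifies the generating
graph. This is a property of the score at these effect sizes, not a
defect of the search.

## The synthetic cohort generator

The generator emulates a cohort of industrial workers whose summary tables
are published but whose records are not: gender split 13.05 % / 86.95 %
(women/men), age quintiles at (0.19, 0.20, 0.19, 0.21, 0.21) on integer
ages 17–66 (uniform within each quintile's bounds), family-history flag at
87.38 % / 12.62 %, and the full 2×5×2 grid of loss-group conditionals.
Printed percentage rows are renormalized to sum exactly to 1 (they carry
±0.01 rounding noise). When audiograms are requested, each record draws a
loss percentage uniformly on its group's interval (group 1 → exactly 0,
group 5 capped at the observed maximum of 67 %) and receives a flat,
symmetric audiogram `25 + pct/1.5` dB HL in both ears, which inverts the
index exactly — so the indexing stage can be exercised end to end and
round-trips to the sampled group.

**What it does not emulate.** Predictors are drawn independently (the
predictor joint was never published); real cohorts have gender–age–history
dependence. Audiograms are flat and symmetric, unlike real noise notches
at 3–6 kHz. There is no noise-exposure covariate, no measurement error,
and no missingness. Passing recovery tests therefore demonstrates that the
estimation and inference machinery is correct and well-calibrated, not
that the fitted conditionals would transfer to any particular real
population; conditional-row recovery is additionally re-verified under a
deliberately correlated predictor sampler to show it does not depend on
the independence assumption.

Note that the published grid itself is not perfectly monotone in age (one
0.44-point inversion for women without family history between the 29–34
and 35–39 groups); the qualitative age-decline test allows for it.

## Cross-validation and AUC

Folds are a seeded random permutation cut into k contiguous blocks (sizes
differing by at most one, e.g. 1418 → 8×142 + 2×141), deliberately
unstratified: the published protocol describes plain disjoint N/k subsets,
and honesty about sparse groups is preserved by flagging a (fold, group)
AUC as undefined when a test fold lacks positives or negatives, never by
substituting 0.5. AUC uses the Mann–Whitney rank form with midrank ties,
`(R₊ − n₊(n₊+1)/2)/(n₊n₋)`, checked to 1e-12 against an all-pairs oracle
and against scikit-learn. The pooled AUC over the joined held-out
predictions is the primary figure; per-fold values are reported alongside.
The AUCs obtainable here describe synthetic cohorts only — the original
study data would be required to reproduce its published accuracy, so those
values are deliberately not asserted anywhere.

## Problem sizes and numerical choices

Recovery runs use 500,000 draws for two-node recoveries and 100,000 per
scenario cell, placing the binomial standard error of a recovered
percentage near 0.03–0.15 points — comfortably inside the ±0.3-point
agreement band while keeping any run under a minute. CPT rows must sum to
1 within 1e-12 (scenario rows within 1e-9 after mixing); the sampler
guards inverse-CDF round-off by clamping to the last state. All entry
points that touch randomness take one explicit integer seed and no global
RNG state is used anywhere.
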