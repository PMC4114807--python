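# Methods

## Consistency model

A printed test result is a triple (statistic string, dfs, p claim). Every
printed decimal is taken to stand for its rounding set: a string with `k`
decimals and value `v` denotes the half-open interval
`[v − u/2, v + u/2)`, `u = 10^−k` (trailing zeros count toward `k`, so
"4.450" is tighter than "4.45"). The statistic→p map is strictly decreasing
in |statistic| for fixed dfs — two-tailed `2·P(T_ν > |x|)` for t, upper tail
`P(F_{d1,d2} > x)` for F — so the image of the statistic's rounding interval
is itself an interval, computed from the endpoint statistics with endpoint
closures tracked explicitly (an interval straddling zero attains |x| = 0 and
p = 1). The p claim denotes its own interval: the rounding interval for
`=`, `(0, b)` for `< b`, `(b, 1]` for `> b`.

A result is **consistent** when the two intervals intersect. This is the
most permissive defensible rule — a result is flagged only when *no*
underlying statistic compatible with the printed one could have produced the
printed p — which minimizes false error flags. The alternative (comparing
the point recomputation to the reported interval) flags results whose only
sin is that the authors rounded the statistic before computing p.

Error taxonomy, applied only to inconsistent results:

* **error** — the intervals are disjoint;
* **large** — |reported p − recomputed p| > .01, using point values (the
  printed p for `=`, the printed bound for `<`/`>`, and the p of the
  printed statistic), since "difference in p" is a point notion;
* **gross** — the claim is significant (its interval lies strictly below
  .05) but the recomputed p is ≥ .05. A printed `p = .05` is *not* counted
  as a significance claim: its rounding interval straddles .05.

Large and gross are nested inside error; a result can be both.

**One-tailed salvage.** A two-tailed recomputation wrongly flags correctly
reported one-tailed tests. When the text within a 100-character window of
the match mentions "one-tailed"/"one-sided" and halving the recomputed
interval restores overlap, the verdict is consistent with a salvage flag so
such results can be tallied separately; `strict=True` disables this. The
window size is a scanning heuristic, not a statistical parameter.

Welch-style fractional dfs are used in the CDF as printed.

## Extraction

The scanner recognizes APA-style layouts `t(df) = x, p ⋚ y` and
`F(d1, d2) = x, p ⋚ y`, with flexible whitespace, optional `*italics*`
markers, Unicode minus/en-dash, optional leading zero in p, and a trailing
`ns` (captured as `p > .05`). Only *complete* reports — statistic, dfs and
p all present — yield results; anything else is skipped and logged. Reports
with material between the statistic and the p value (e.g. an effect size)
are deliberately out of regex scope: gap-tolerant patterns produce wrong
captures, and such results enter through the manual-entry CSV instead.
Decimal commas are not supported. Printed strings are preserved exactly so
downstream rounding intervals are faithful.

## df screen

Expected df is `N − 2` (independent two-sample) or `n − 1`
(paired/one-sample) after subtracting *disclosed* exclusions and
missingness; design labels come from the metadata table, never from text
mining. Any exact integer mismatch is a discrepancy — zero tolerance, since
a deficit of even one case is evidence of an undisclosed exclusion.
Fractional dfs and unknown designs are indeterminate, never discrepancies.
Because the test-to-study mapping inside an article is not recoverable from
text, a t test counts as matching when *any* described study's expected df
agrees; this can only miss true deficits (a deficit coinciding with another
study's df), never invent them, so the screen's false-positive rate on
clean articles is exactly zero.

## Article level

Only results whose printed claim lies strictly below .05 are included.
Each retained article contributes the median of recomputed p values over
included results (point recomputations, also where only `<` bounds were
printed), error counts over included results, and the median of its
per-study total sample sizes. Medians use the standard midpoint convention
for even counts. Articles with no included result are dropped with a logged
reason. Group/journal tallies carry statistic-level and article-level
counts with percentages (one decimal at statistic level, whole percent at
article level); totals are asserted to equal the column sums on every run.

## Comparison suite

* **Wilcoxon rank-sum** (W = rank sum of group 1 = U₁ + n₁(n₁+1)/2):
  exact enumeration for tie-free samples up to n = 25 per group, otherwise
  the normal approximation with midranks, tie correction and continuity
  correction. Degenerate all-equal data give p = 1.
* **Permutation null for W**: articles are reassigned to groups uniformly
  with group sizes preserved; the empirical p uses the add-one convention
  `(1 + #extreme)/(reps + 1)` so it is never zero. Two-sided extremeness is
  `|W − E[W]| ≥ |W_obs − E[W]|` with `E[W] = n₁(n+1)/2`. An exhaustive mode
  enumerates all `C(n, n₁)` assignments and returns the exact permutation p.
  Permutations are unrestricted (no journal stratification), matching the
  plain reassignment design. Default two-sided, with one-sided options.
* **Negative binomial regression** (NB2, maximum likelihood via
  statsmodels): `E[count] = exp(b0 + b1·group + b2·log n_statistics)`,
  dispersion α with `Var = μ + αμ²`. (R's `glm.nb` reports θ = 1/α.) On
  non-convergence or a degenerate dispersion the model falls back to
  Poisson with a warning; all-zero counts raise, and the caller falls back
  to Fisher exact tests on article-level flags — run for all, large and
  gross error counts separately.
* **Fisher exact** (two-sided, hypergeometric rule: sum of table
  probabilities ≤ the observed table's): delegated to scipy and
  cross-checked in the tests against brute-force enumeration. Zero margins
  give p = 1.
* **Power simulation**: per replicate, n values from N(0, 1) versus n from
  N(d, 1), two-sided rank-sum at α; the estimate is the rejection fraction.
  At d = 0.5, n = 90/group, α = .05 the simulated power is ≈ .90.

All Monte-Carlo procedures take a single integer seed and are reproducible.

## Synthetic corpus

The generator emulates the study conditions of a two-group literature
corpus; its defaults are fixed, not tuning knobs:

* 92 vs 61 articles across six journal tags (weights matching the observed
  per-journal article counts);
* significant results per article: zero-truncated negative binomial with
  means 19.4 / 14.5 and per-group dispersion (1.0, 1.8), calibrated by
  simulation so realized medians land at ≈ 14 and 12;
* per-study total N: lognormal, median 80, σ = 0.5, clipped to [20, 500]
  (per-article median sample sizes land in the 70–90 range);
* mechanistic results: effect size d ~ N(0.5, 0.2²) truncated at 0.05,
  statistic drawn from the matching noncentral t or F distribution
  (t: df = N−2, ncp = d√N/2; F: d1 ∈ {1,2,3}, df2 = N−d1−1, λ = Nd²/4),
  true p computed from the central distribution, kept when significant.
  Sampling statistics rather than p values keeps statistic/df/p coherent —
  which the checker requires — and yields the right-skewed significant-p
  distribution seen in real corpora;
* error injection per result at rates .040 / .010 / .011
  (small / large / gross), matched to observed per-statistic error shares
  (≈ 6–7% total, ≈ 1% large, ≈ 1% gross). Rates are modulated by an
  article-level gamma propensity (mean 1, variance 0.8), so per-article
  error counts are genuinely overdispersed — the regime the negative
  binomial regression exists for — while marginal rates are unchanged.
  Every perturbed result is passed through the consistency checker before
  being written, so the recorded class always equals what the pipeline can
  recover: small means inconsistent but within .01 and still significant;
  large means off by more than .01 but significant both ways; gross means
  a truly non-significant result printed as significant;
* undisclosed exclusions in 41% of articles: a deficit of 1–3 cases is
  removed *before* the statistic is drawn (df, statistic and p all reflect
  the reduced n), while the metadata still describes the full N — exactly
  the signature the df screen hunts;
* prose templates vary spacing and italics markers to exercise the
  scanner's dialects.

What the generator does **not** emulate: non-APA layouts (effect sizes
between statistic and p), decimal commas, dependence between results beyond
the shared error propensity, journal-specific error cultures, or the
data-analytic act of outlier removal itself — only its downstream
signatures (p distribution, reporting errors, df deficits). Passing
recovery tests therefore show the pipeline is correct on well-formed
APA-style corpora, not that a regex audit of arbitrary PDFs is complete.

## Problem sizes and numerical choices

The test suite uses 200–600-article corpora for recovery checks, 10,000
generated results for the grid-search oracle comparison, 200 replicates for
count-regression coverage, 2,000 replicates for null calibration, and
10,000 replicates for the power target — sizes chosen so each check is
statistically decisive at desk scale. Tolerances on stochastic checks are
derived from the generative model (binomial or binomial-plus-clustering
bands at 99%), never eyeballed. Interval endpoints are compared exactly in
floating point; the only numeric tolerance inside the implementation is the
1e-9 slack used when comparing permutation statistics for extremeness.

## Known limitations

* The scanner requires period-decimal English APA layout; everything else
  must come through the manual-entry table.
* The consistency rule is interval overlap; tools that compare the point
  recomputation against the reported interval will flag slightly more
  results. Both conventions agree on every gross error.
* The df screen cannot see exclusions that leave df consistent with some
  other described study, and treats subgroup analyses as indeterminate
  unless subgroup sizes are supplied.
* Whether an article "removed outliers" is metadata supplied by the user;
  the package does not text-mine analytic decisions.
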