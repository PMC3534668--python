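# Methods

## The model

`stemnet` studies how usage concentrates on a few pluripotent stem-cell
lines.  The empirical object is a bipartite *usage network*: published
studies and cell lines are the two node classes, and an edge joins a study
to every line it experimentally used.  A line's degree is its usage
frequency; the observed degree distribution is strongly heavy-tailed, with
the earliest-derived lines (H1, H9 and their contemporaries) dominating.

The generative model is a cumulative-advantage (Yule–Simon) process adapted
to bipartite growth.  One bootstrap project creates `F` founder lines.
Each subsequent study uses exactly `N` distinct lines; `k ~ Binomial(N, p)`
of them are newly derived, and the remaining `N − k` are drawn from
existing lines with probability proportional to each line's prior usage
count.  Three modelling conventions matter and are fixed here:

- **Counts are frozen within a study.**  A study's own usage does not feed
  back into its own draws; "previously used" means *in other studies*.
- **A line enters the pool with weight 1**, its introducing edge.  Founder
  lines likewise start with their bootstrap edge.  (The alternative —
  weight 0 until first reuse — never lets an unused line be rediscovered
  under pure proportionality and is not used.)
- **If the pool is smaller than `N − k`** (possible only in the first
  studies when `F < N`), the deficit is covered by extra novel lines so
  that every study uses exactly `N` distinct lines.

These give exact conservation laws used as tests: a run with `S` studies
has exactly `F + N·S` edges, and `F +` (total binomial novel draws) lines.
For large `S` the degree tail approaches a power law with exponent
`1 + 1/(1 − p)` (≈ 2.18 at `p = 0.15`), which ties the simulator to the
estimator below.

Reference parameter values: `N = 2` (close to the observed mean of 2.47
lines per publication), `S = 2,927` (so that `2·S` matches the empirical
citation total), `F = 5` founders, and `p = 0.15`, chosen from the
candidate grid 0.05–0.30 by distance between simulated and observed usage
curves rather than by formal likelihood.  Ensembles of independent
replicates (reference size 1,000; 200 in the shipped analyses and tests,
which keeps every run under a few seconds without visibly changing any
quantile reported here) supply the distributions against which observed
statistics are placed.

## Exponent estimation

Line-usage tails are fitted with the discrete (zeta-normalized) power law
`p(x) = x^(−α) / ζ(α, xmin)` at a **fixed** cutoff `xmin = 3`; values below
the cutoff are discarded and no automatic cutoff selection is performed.
The MLE is found by bounded scalar minimization of the negative
log-likelihood over `α ∈ (1, 20]` (tolerance 1e-10), with the Hurwitz zeta
evaluated by `scipy.special.zeta`.  The closed-form approximation
`1 + n / Σ ln(x_i/(xmin − ½))` is reported as a diagnostic.  Degenerate
input (all tail values equal to `xmin`) makes the likelihood increase
without bound; the fit is flagged `diverged` and the search bound is
reported with a warning.  Goodness-of-fit p-values by semiparametric
bootstrap are deliberately out of scope — at a few hundred tail
observations they would not be reliable.

## Model-vs-data comparison

The usage curve `c(k)` = number of lines used at least `k` times is
compared by the area enclosed between curves on the integer usage grid,
`Σ_k |a(k) − b(k)|`, on the raw count scale by default (a log10 option
exists because such curves are conventionally drawn on log axes; the
default is the untransformed area).  This distance is a metric; the
replicate minimizing it is the "best fit", with ties broken by replicate
index so the choice is order-independent.  Observed statistics (fitted α,
maximum degree, line count, largest-component size) are reported with
mid-rank percentiles within the ensemble.

## Outlier detection

Usage declines roughly exponentially with a line's year of first
publication.  The trend is fitted by Huber M-estimation (tuning constant
1.345, MAD residual scale, IRLS to 1e-8 relative coefficient tolerance —
the standard defaults of robust regression software) of log usage on
first-publication year; natural logs are used, and both the inverse
prediction and the z-scores are invariant to the base.  Inverting the fit
gives a *predicted* first-publication year from usage alone; the gap
`actual − predicted` measures how much more a line is used than its
publication age explains.  A per-cohort z-score standardizes log usage
among lines first published the same year (sample SD; cohorts of size 1 or
zero spread get z = 0 with a warning rather than exclusion, so every line
stays in the report).  Thresholds: gap ≥ 4 years and z > 2.  A line is
reported an outlier when **both** fire; with ~1,000 heavy-tailed lines the
z-threshold alone necessarily passes a few percent, and the conjunction is
what isolates the handful of genuinely anomalous lines.  Note the
calibration subtlety: cumulative advantage itself occasionally produces
"lucky" late lines, so even clean model-generated corpora show a small
(~1–2%) joint-flag rate; the planted-outlier experiments (usage inflated
20× relative to cohort) are recovered at 5/5 with false positives well
under 5%.

## Enrichment

The unit of analysis is the study: it "uses" the category if at least one
of its lines was formerly eligible for US federal funding (derived in or
before 2001).  Over-representation within a subset (a funder's portfolio,
a country, a time window) is tested with the one-sided hypergeometric
upper tail `P(X ≥ k)`, accumulated from log-pmf terms via logsumexp for
stability.  No multiple-testing correction is applied per comparison (a
Bonferroni helper is provided as supplementary output).  The published
share tables (185 CIRM-funded studies and their 75-study NIH-free subset;
201 hiPSC reuse studies by lab provenance) are shipped as exact count
fixtures; shares are printed at one decimal.

## Country clustering

Countries with at least 30 publications receive a usage profile (studies
per line); distances are `1 − ρ_Spearman` with mid-rank ties, and profiles
are agglomerated by UPGMA.  UPGMA is implemented directly (the merge rule
is ten lines of arithmetic) so that ties can be broken deterministically
by lexicographic cluster label; `scipy.cluster.hierarchy` serves as an
independent cross-check in the tests on tie-free matrices.  Profiles use
raw counts, not per-country frequencies — the two give identical Spearman
distances (rank-invariant rescaling within a row), which is itself a test.

## The synthetic corpus

The curated literature corpus is not publicly deposited, so a generator
produces structurally faithful stand-ins: per-study line counts
`1 + Poisson(1.47)` (mean 2.47), usage grown by the cumulative-advantage
engine itself (the analysis's null structure *is* that model), publication
years 1998–2011 assigned along a 35%/year growth curve of publication
volume, line derivation years lagging first publication by `Poisson(1)`
years, formerly-approved status for lines derived in or before 2001, a
14-country profile dominated by the US (35%), and independent CIRM (8%)
and NIH (40%) funder tags.  Under the default **policy-independent null**,
country and funders are assigned independently of which lines a study
used.  A `policy_bias` switch multiplies the odds that a study using a
formerly approved line is assigned to the bias country, giving the
enrichment stage a controlled alternative for power experiments.

What the generator does *not* emulate: real nonstationarity of novelty
rates, multi-country collaborations, correlated funder–country structure,
and curated line-name aliasing.  Tests passing on synthetic corpora
therefore demonstrate correctness and calibration of the pipeline, not
empirical claims about the literature.

## Problem sizes and determinism

Shipped analyses use 2,000-study corpora, 200-replicate ensembles,
400 null corpora of 300 studies for calibration, and 60 biased corpora of
250 studies (~150-study subsets) for power — sizes at which every reported
quantile is stable to well within its sampling spread.  All randomness
flows through `numpy.random.Generator` objects seeded from a single
integer via `SeedSequence.spawn`, so every table, ensemble and experiment
is exactly reproducible from one seed.

## Known limitations

- The empirical headline numbers (2.47 lines/study, α = 1.94, max degree
  996, 794 lines in the main component, the seven flagged lines) depend on
  the undeposited corpus; they are recorded as documented reference
  constants (`stemnet.reference`) and used only for context, never
  asserted as recomputed results.
- The published analysis is internally inconsistent on its line count (955
  in the text, 995 in the figure caption); the pipeline always reports its
  own n.
- Whether the empirical mean of 2.47 was computed on the main component or
  the full network is ambiguous in the source; both statistics are exposed.
- `p` is selected by curve comparison over a grid, not estimated by
  likelihood; the model is one plausible generative account, not a tested
  hypothesis against alternatives.
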