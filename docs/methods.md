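# Methods

`seekpaths` models how people seek cancer information on the web: a
cohort of intensive searchers is distilled from a raw query log, their
page-category journeys are described by discrete-emission hidden Markov
models, and their social context is analysed through co-searching
contacts. Because real search-engine logs of this kind are private, the
package is organised around a synthetic-data generator that reproduces
the reported statistical structure of such logs, and every analysis
stage is validated by recovering the generator's parameters.

## The data model

A *query log* is a table of page visits: anonymised user id, day within
a 92-day study window, query text, visited page id, and the page's
thematic category — one of ten canonical tokens (`causes`, `prevention`,
`symptoms`, `information`, `treatment`, `social_media`, `support`,
`celebrity`, `pets`, `other`). A *contact list* is an undirected edge
list over a user universe (an instant-messenger roster); only a
minority of that universe ever queries cancer. A *lexicon* provides 35
common cancers with synonyms, age-adjusted incidence per 100,000,
age-adjusted 5-year relative survival (%), and median age at diagnosis.

Cancers are split at the median 5-year survival across the lexicon:
strictly below the median is *aggressive*, the rest *indolent*.

## Cohort rules

Queries are matched to the lexicon by case-insensitive word-boundary
search over names and synonyms (no stemming; a query naming several
cancers counts once toward each). Events on pages of unknown category
are dropped before any counting — the analysis lives on the categorised
page universe, and an open alphabet would break the journey models.
A user enters the cohort with at least `min_pages = 5` categorised
cancer-related page visits spanning at least `min_categories = 2`
categories. The *dominant disease* is the cancer the user queried most
often (ties: lexicographic name), and it fixes the user's severity
stratum. The *search period* is the inclusive day span between the
user's first and last cancer-related visit.

## Journey models

A user's category sequence is modelled as a K-state hidden Markov chain
with categorical emissions over the ten categories. Training is
Baum–Welch with scaled forward–backward recursions, batched across
users; the log-likelihood is asserted non-decreasing at every iteration
and training stops at a relative improvement below 1e-6 or 500
iterations. Emission rows receive an additive pseudo-count of 1e-3 per
M-step so held-out tokens never hit probability zero. The initial state
distribution is estimated freely, which absorbs the fact that a user's
journey may have begun before the observation window.

Each EM run starts from a randomised *anchored* initialisation: the
first min(K, 10) states are seeded on distinct high-frequency
categories (order jittered per restart) and the transition matrix on
soft bigram counts under that anchoring, with multiplicative noise.
Purely random starting points converge to merge/split local optima on
sharply structured sequences often enough that five restarts cannot
always rescue the fit; anchoring breaks that symmetry while keeping
restarts genuinely random. A fully random initial model can still be
supplied explicitly.

The number of states is chosen by holdout: users (not events) are split
75/25, models for each candidate K are fitted with 5 random restarts,
the restart with the highest *training* log-likelihood is kept (restart
selection never sees the test set), and the chosen K minimises the
one-step-ahead argmax prediction error on held-out users — the fraction
of positions, from each sequence's second onward, where the filtered
predictive argmax misses the observed category. Ties go to the smaller
K. Argmax ties break in canonical category order. A per-event
predictive log-loss is available as an alternative metric.

Fitted models are summarised by their *signature outputs* (categories
emitted above 0.05 per state, ranked) and a *stability ranking* (states
ordered by self-transition probability).

## The synthetic generator

`SyntheticConfig` defaults encode the study conditions the package is
calibrated to:

| parameter | default | meaning |
|---|---|---|
| `pageview_exponent` | −2.19 | discrete power-law slope of pages per user (xmin = 1, truncated at 10⁴) |
| `pagepop_exponent` | −2.25 | users per page |
| `degree_exponent` | −0.99 | contacts per user; upper truncation solved so the lower median is `target_degree_median` = 6 |
| `mean_search_days` / `sd_search_days` | 10.0 / 14.5 | lognormal (method-of-moments) search-window length, rounded and clipped to [1, 92] |
| `multi_category_fraction` | 0.415 | share of users whose journey spans ≥ 2 categories |
| `pair_enrichment` | 6 | co-search pairs as a multiple of label-permutation chance |
| `overlap_prob` | 0.56 | probability an acquaintance shares the proband's dominant disease |
| `lag_aggressive_days` / `lag_indolent_days` | 9 / 15 | mean acquaintance onset lag (exponential, at least one day) |
| proband durations (agg/ind) | 11.0 ± 14.7 / 13.9 ± 18.9 | lognormal, per severity |
| acquaintance durations (agg/ind) | 12.5 ± 17.3 / 5.1 ± 8.1 | lognormal, per severity |
| `incidence_r2_target` | 0.72 | share of query-share variance attributable to incidence |
| `network_scale` | 4 | contact universe as a multiple of the searcher population |

Disease popularity is incidence plus Gaussian noise scaled so incidence
explains about `incidence_r2_target` of the query-share variance.
Power-law sampling is inverse-CDF on the zeta-normalised pmf. The
contact graph is a configuration model (stub pairing; self-loops and
parallel edges dropped, a ~0.3% perturbation). Event days are uniform
within each user's window with the endpoints pinned, so the realised
search period equals the drawn window length exactly.

`network_scale` exists because a messenger graph spans everyone while
only a fraction query cancer. Compressing the universe to the searcher
population would force the within-cohort edge density so high at 6×
enrichment that nearly every included user would sit in a pair,
contradicting the separately specified global mean search period.

Co-search structure is planted in two steps. First,
`(pair_enrichment − 1)` times the analytic label-permutation
expectation `E·m(m−1)/(N(N−1))` worth of edges between unused
gate-passing users is added *on top of* the chance pairs that occurred
naturally (solved self-consistently, since added edges enlarge E;
planting relative to the realised chance count rather than up to a
target total keeps the fold unbiased, in particular exactly calibrated
at enrichment 1). Then *every* qualifying component — planted and
chance alike — is oriented by breadth-first search from its
highest-degree node: the root is the proband (proband duration, own
disease), every child an acquaintance (acquaintance duration, onset lag
along the tree edge, disease copied from its parent with probability
`overlap_prob`, otherwise forced distinct). Typing chance components
too keeps pair statistics clean: at 6-fold enrichment one pair in six
arises by chance, enough to distort stratum means if left untyped.

### Ground-truth journey models

The two severity truths (five states each) are the package's design;
they mirror the qualitative contrast they are meant to exhibit.
The *aggressive* truth is strictly string-like — each phase
(symptoms → information → causes → treatment → wrap-up) hands over only
to the next, with a treatment↔wrap-up cycle at the end — its first two
states are the most stable, treatment appears late, and `support` is
never emitted. The *indolent* truth is interconnected with roughly
symmetric transitions, its last three states are the most stable,
treatment appears early, and one state carries a strong `support`
signature. Emission supports are disjoint across states (each category
belongs to one phase; two categories per state), so the journey phase
is essentially readable from the page stream. That near-observability
is deliberate: it is what makes the state count recoverable by holdout
prediction — merging two phases forfeits a distinct dominant
prediction, while extra states change no prediction and lose the
parsimony tie-break. Real journeys are noisier than this; the
recovery results certify the selection machinery, not the
identifiability of any real log.

Role preferences (probands toward treatment +25% and information +14%;
acquaintances toward causes +116% and social media +75%) are planted by
*occupancy tilting*: transition and initial probability flowing into a
state is scaled by `1 + (f−1)·P(category | state)` and renormalised,
shifting time spent in the relevant phases without touching emissions.
Probands also query more distinct cancers (Poisson extras, rate 0.9 vs
0.5) — secondary-disease queries replace interior events so window
endpoints keep the dominant disease.

Multi-category users whose sampled sequence happens to be constant are
resampled (up to ten attempts), so the configured multi-category
fraction is what the cohort gates actually see.

### What the generator does not emulate

Query texts are templated (`<cancer name> <topic word>`), not natural
language; page ids have no content; intra-day event order is arbitrary
and the events-per-day profile is uniform within the window; labeler
errors are uniform over wrong categories; contact degrees are
independent of search behaviour except through planting. Tests passing
on this generator certify the estimators' correctness and calibration,
not their behaviour under real-log pathologies (spam, shared devices,
ambiguous natural-language queries).

## Power-law fitting

`fit_loglog_slope` regresses log10 frequency on log10 value over the
unbinned count histogram (base-10, xmin = 1, no logarithmic binning),
restricted by default to the histogram's *dense prefix* — observed
values up to the first gap in integer support, further trimmed of
trailing values whose frequency is below 1% of the histogram's peak.
Beyond that region expected counts are dominated by Poisson noise and
eventually degenerate into a flat band of singletons, which biases the
full-range slope severely toward zero (a −2.19 truth at n = 50,000 fits
near −1.2 with the tail included) and leaves the fit at the mercy of
single high-leverage boundary points. With the dense-prefix rule the
estimator recovers generating exponents in [−3, −1.5] with
|bias| ≲ 0.01 and R² ≈ 1.0. Exact small histograms are unaffected. A truncated discrete MLE is
provided as a cross-check only. The lower median (the ⌈n/2⌉-th order
statistic) is the reported central value for degree distributions.

## Social statistics

The chance model for co-searching is label permutation: the contact
graph is held fixed and the "included searcher" labels are reassigned
uniformly over the node universe, preserving the cohort size; the
enrichment fold is observed pairs over the permutation mean, with a
one-sided permutation p-value ((1+#{null ≥ obs})/(n+1)). Overlap is
benchmarked against uniformly random cohort pairings (10,000 draws).
Group contrasts use the rank-sum test (lags between severities,
category shares between roles), the paired sign test (proband vs
acquaintance durations within pairs) and the signed-rank test (number
of distinct diseases per role), all two-sided; strata under two pairs
are flagged and skipped rather than tested.

First-searcher designation on tied first days goes to the endpoint with
more pages, then the smaller id. A pair's severity stratum is the first
searcher's.

## Crowd-label aggregation and ambiguity

A page is decided by a ≥3-of-5 vote; otherwise its pattern (2+2+1,
2+1+1+1, five singletons) is recorded. For the ambiguity analysis,
pages are embedded as term-frequency vectors (lowercased, English stop
words removed) and compared with centroids (means) of decided pages per
category using cosine distance; the per-page statistic is the relative
spread (max − min)/mean of its distances to the categories its labelers
voted for, contrasted between decided and ambiguous pages by rank-sum
test. The distance metric and spread statistic are package choices —
they are used only comparatively.

## Epidemiological regression

Query shares (per included user by dominant disease; per-query
weighting available) are regressed jointly on incidence, 5-year
survival and median age at diagnosis by OLS with intercept. A constant
response returns R² = 0 by convention; condition numbers above 1e8
flag near-collinear designs.

## Problem sizes

Validation and acceptance runs use scaled-down populations chosen so
every estimate is measured well inside its tolerance: 2,000 users
(sequence lengths 5–30) for state-count selection; 50,000 draws for
slope recovery; 20,000 users (contact universe 80,000) for enrichment;
a population sized to yield ~20,000 included users for the search-period
mean; 200,000 users for the acquaintance-duration check (≥ 1,000
indolent pairs). The real study's population (232,681 screened users)
is not reproduced; counts that depend on it are out of scope.

## Known limitations

* The permutation null treats inclusion as exchangeable across the
  universe; a degree-preserving rewiring null is a natural alternative
  and is not implemented.
* Acquaintances reached through longer chains inherit onset lags that
  accumulate along the tree, so realised lag means sit slightly above
  the configured per-edge means.
* The lognormal window model rounds to whole days and truncates at the
  study window, biasing the realised mean by about −0.2 days at the
  default parameters.
* Holdout selection inherits the randomness of EM restarts; with few
  sequences (≲ 100 per stratum) the error curve's plateau can tie in
  favour of a neighbouring K.
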