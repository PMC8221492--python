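# Methods

This note documents the statistical machinery, the choices made where the
cited estimator families leave details open, and what the synthetic studies
do and do not demonstrate.

## Data model

A *sampling occasion* is a calendar day with any photo-identification
effort; days without records are absent from the occasion list, so rate
estimators never treat no-effort days as absences. An *encounter* is a
unique observation of a unique group on one day: identical member sets
repeated within a day collapse to one encounter, while a different member
set the same day is kept. Behavior labels are drawn from a fixed vocabulary
(`bubble_net`, `feed_other`, `travel`, `rest`, `sleep`, `robust`, `social`,
`other`); unknown codes map to `other` with a warning. Individual IDs are
opaque strings — no fuzzy matching.

Annual summary semantics (matching the arithmetic of standard capture
tables): total identifications are individual-day captures; within-season
recaptures are `total − unique` (identifications of individuals already
seen that season), as a percentage of total identifications; prior-year and
any-prior-year recaptures are counts of unique individuals, as percentages
of unique. The annual return rate is the prior-year recapture share; the
first season can be included as a zero (an option, because both conventions
appear in the literature and they differ by a few points in the multi-year
mean).

## Lagged identification rate (LIR)

`LIR(τ) = Σ m(t, t+τ) / Σ n(t) n(t+τ)` over same-season day pairs, where
`m` is the number of individuals identified on both days and `n` the number
identified per day. Lags are capped at 230 days and restricted to pairs
within one season. A lag is retained when its denominator (the number of
paired identifications) reaches `min_pairs = 10`. Bootstrap CIs resample
individuals with replacement (default 100 replicates); the numerator is
linear in resampling weights, which keeps the bootstrap cheap.

The null model of random movement permutes each individual's capture days
uniformly over that season's effort days, preserving per-individual capture
counts and the effort set exactly (verified each iteration in tests). The
envelope is the 2.5/50/97.5 percentile band; residency is significant at
lags where the 10-day running mean of the observed curve exceeds the upper
band.

Decay models are fitted to octave-pooled points (bins centered at
τ = 2⁰…2⁸, pooled by weighted mean with weights equal to paired
identifications) by weighted least squares: closed (`R = 1/N`),
emigration/mortality (`R = e^(−τ/a)/N`), emigration + reimmigration
(`R = (b + (1−b) e^(−τ/a))/N`), and the latter times an extra mortality
decay. Positive parameters are fitted on the log scale, `b` on the logit
scale; each richer model is additionally seeded from its nested parent and
a final guard substitutes the parent solution if the optimizer does worse,
so raw fit never degrades with added parameters. Ranking uses a
small-sample corrected information criterion on the least-squares deviance,
`n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1)`; the exact quasi-likelihood weighting
used by legacy desktop tools is not published, so agreement is validated by
parameter recovery on synthetic data rather than against their output.

## Site-fidelity indices

Per individual-season: occurrence = capture days / effort occasions;
permanence `I_T` = exclusive capture span / exclusive season span;
periodicity `I_t` = capture days / inclusive capture span;
`SSFI = 2/(1/I_T + 1/I_t)`. The mixed span conventions are deliberate: they
make a full-season daily-captured individual score exactly 1 on all three,
an individual seen only on days 1 and N score `I_T = 1`, `I_t = 2/N`, and a
single-capture season score `I_T = 0` hence `SSFI = 0` (maximally
non-resident), flagged `single_capture`. The cited index family's source
formulas are not restated in full anywhere accessible, so these
operationalizations are pinned by the boundary cases above and tested as
such. `minimum_stay` is last − first capture day (exclusive; an inclusive
flag exists).

## Associations

`SRI = x/(x + y_A + y_B + y_AB)`: the denominator is the number of occasions
at least one member was identified. Dyads never jointly sampled (`d = 0`)
are undefined and excluded, not zero. Individuals qualify with ≥ 5
occasions (≥ 10 for lagged association rates).

**Data-stream permutations** are chained within-day group swaps: a move
draws a day with ≥ 2 groups, two groups, one member of each, and exchanges
them, preserving the day's group-size multiset and each individual's daily
presence. Defaults: swaps per iteration = total number of observed groups;
burn-in = 10× that. The together-count matrix is updated incrementally per
swap (exactness against full recomputation is tested), so thousand-iteration
chains are cheap. When no day has two groups the stream degenerates to the
identity with a warning. P-values use the add-one convention
`(count + 1)/(n_iter + 1)` throughout the package.

The population-level association test compares the SD of observed SRIs to
the permuted SDs (one-tailed high): excess SD means strong and weak bonds
both exceed random association-dissociation dynamics.

**LAR**: `LAR(τ)` = (dyads grouped at t and at t+τ) / (dyads grouped at t
whose member is identified at t+τ), over same-season day pairs. The
"identified later" denominator counts dissociation only when observable,
avoiding detection bias. Social-process models (constant companions;
casual acquaintances `c·e^(−τ/a)`; constant + casual; two-level casual)
are fitted with the same pooling, seeding, and ranking machinery as the
LIR models. The data-stream null supplies the LAR envelope.

**Social differentiation.** The latent true index αᵢⱼ follows a
Beta(mean μ, CV S) distribution; observed together-counts are
Poisson(dᵢⱼ αᵢⱼ) — the Poisson approximation to binomial sampling of
occasions. (μ, S) maximize the marginal likelihood, evaluated by
Gauss–Legendre quadrature on the logit scale where the Beta transforms to a
smooth unimodal density for every shape pair; everything stays in logs so
extreme concentrations neither over- nor underflow. The observed-true
correlation is `r = √(Var_true / (Var_true + mean(μ/d)))`, the power rule
of thumb is `S²·H > 5` with `H` the mean identifications per individual,
and a flat-likelihood flag probes ±20% perturbations of S. The exact
internals of the legacy implementation of this estimator are unpublished,
so the Beta–Poisson marginal is validated by simulation recovery
(monotonicity across a CV grid; |bias| ≤ 0.15 at CV 0.8, d = 20).

## Affiliations (GAI)

Dyadic association counts x out of d are regressed on three structural
predictors with a binomial GLM; the GAI is the signed deviance residual.
Predictors: joint gregariousness = log of the product of each partner's
summed SRI excluding the focal dyad (sums floored at 10⁻⁶ before the log so
isolated individuals stay finite); geographic overlap = share of
co-identified years with yearly mean positions within 15 km (undefined for
dyads with no shared years — excluded from the regression); temporal
overlap = co-identified years over years either was identified. Yearly mean
position per individual is the representative location (encounter-level
granularity is not preserved in the yearly overlap definition). Preference
tests refit the regression on every data-stream permutation (recomputing
gregariousness from the permuted associations; the overlap predictors are
permutation-invariant) and compare, per subnetwork, the prevalence of
observed GAIs above their dyad-wise null 95th percentiles and the GAI
standard deviation, both one-tailed high.

## Network structure

Networks take all non-zero SRIs among qualifying individuals as weights
(negative affiliation weights are zeroed where positive-network analyses
require it); isolated nodes stay in the graph. Louvain runs at resolution
1.0 with 10 seed-controlled restarts, keeping the best modularity (ties to
the fewest communities). Modularity is recomputed independently from the
direct formula in tests to 10⁻⁹. Structural nulls rebuild the network and
re-detect communities on each data-stream permutation: modularity tested
one-tailed high, community count two-tailed. The running window re-runs
everything on each block of consecutive seasons (individuals re-qualified
within the window; each window's null randomized independently) and tracks
Q, K, and the population share of the five largest communities.

## Niche congruency

Traits per individual: mean/SD fjord position, behavior rates (share of the
individual's encounters exhibiting each behavior), years-seen fraction,
mean arrival day, mean minimum stay, mean SSFI. Traits are z-scored over
the analyzed individuals before any variable subsetting. k-means uses 10
starts and ≤ 100 iterations with k pinned to the social community count.
The congruency statistic is the Adjusted Rand Index (the raw fraction of
congruent dyads is reported alongside but ARI, being chance-corrected, is
authoritative). Forward null: shuffle social labels (sizes preserved);
reverse null: independently permute each trait variable and re-cluster.
Subset sweeps enumerate all 2^p − 1 variable subsets (p ≤ 12), rank by ARI,
and score variable importance as the share of significant subsets including
the variable.

**Behavior transference.** Dyads seen together on ≥ 3 occasions are split,
per primary behavior, into practitioners (≥ 1 joint encounter exhibiting
it) and others. The statistic for a secondary behavior is the mean of
10,000 bootstrap differences (one random practitioner's rate minus one
random other's). The null permutes encounter-level behavior annotations and
recomputes the statistic 1,000 times; since the bootstrap mean's
expectation is exactly the difference of group means, the null statistics
use that closed form, removing Monte-Carlo noise from the null without
changing its distribution. The reported p is the fraction of null values at
or below the observed mean: p < 0.025 ⇒ practitioners significantly *less*
likely to share the secondary behavior, p > 0.975 ⇒ *more*. The matrix is
asymmetric by construction and is never symmetrized; behaviors absent from
the dyad set are untestable (NaN).

## Assortativity and network positions

Continuous assortativity is the edge-weighted covariance of endpoint trait
values over the endpoint variance (each undirected edge entering in both
orientations); categorical assortativity is the weighted mixing-matrix
form. Both run separately on the positive-GAI network and the
|negative-GAI| network (magnitudes as weights, sign tracked for
interpretation). Node-shuffle nulls report both one-sided tails plus
"more/less extreme than expected" readings of |AC| for the avoidance
network. Position metrics: weighted degree, contact count, generalized
betweenness with edge cost `(1/w)^α` at α = 0.5 (α = 0 recovers binary and
α = 1 inverse-weight betweenness — both limits tested), harmonic closeness
(unreachable pairs contribute zero — chosen because these networks have
isolated components and the classic component-restricted closeness is not
comparable across components), and the weighted local clustering
coefficient. Position ~ trait tests compare least-squares slopes to
trait-shuffle nulls, two-tailed via the 0.025/0.975 quantiles.

## Geography

Fjord position is the shortest around-island swimming distance (km) from a
location to the fixed inland reference, computed on a user-supplied
navigable-waterway graph after snapping to the nearest waypoint (an error
names the distance when the snap tolerance is exceeded). Synthetic data
carry positions directly; the graph path is exercised on fixture graphs.
Behavior-rate tests pool encounters into half-open 10-km bins over 0–100 km
(the last bin closed; beyond-range encounters excluded and counted),
permute the variable across encounters holding bin occupancy fixed, and
flag bins outside the 95% envelope; numeric variables use bin means. The
per-encounter position is the encounter's own location (the mean of member
records), not a member average across encounters.

## Synthetic generator

One root seed drives four spawned streams (presence, grouping, detection,
annotation), so the output is byte-identical given the seed. Each season a
community-specific fraction returns; arrivals are Normal(community mean,
10 d); residency is exponential (default mean 20 d, matching typical
documented fjord occupancy); each day the animals present are partitioned
by one-pass seeding — join a group holding a community-mate with weight
`w_in` (default 8), any other group with `w_out` (default 1), or open a new
group with weight 6 (chosen to give realistic group sizes of ~1–4) — and
each group is detected with probability 0.8. Detected groups get one
behavior from the seeder community's distribution and a position
Normal(community mean, 10 km) clipped to 0–100 km; community behavior
distributions shift from other-feeding/social inshore to bubble-net-heavy
offshore, and outer communities arrive earlier, mirroring the trait
gradients the analysis targets. Defaults (200 individuals, 7 communities,
5 seasons of 60 days) are the strong-signal study conditions used for
recovery checks.

The generator is a statistical emulator, not a movement model: it produces
group compositions, annotations, and detection gaps with the right
dependence structure, but no spatially explicit movement, no demography
beyond annual return, and — important for interpretation — group-level
annotation sharing means co-members have identical per-encounter positions
and behaviors, a stronger within-group correlation than field data. Tests
passing on it show the estimators and nulls are correct and well
calibrated under the assumed structure; they do not show the field data
satisfy that structure.

## Validation studies

- **Calibration**: 200 scaled-down null replicates (30 individuals, 2×25-day
  seasons, `w_in = w_out`, common trait parameters), 200 permutations per
  test; each framework's rejection rate at α = 0.05 must lie in
  [0.02, 0.09]. The independence condition is enforced by permutation:
  trait columns are shuffled independently across individuals and behavior
  annotations across encounters before testing. This matters because traits
  computed from shared group annotations are intrinsically correlated with
  network position (co-members share each encounter's annotation), so
  node-shuffle tests on *raw* trait tables over-reject even when grouping
  is community-blind — a property of such data worth keeping in mind when
  interpreting node-permutation tests on real photo-ID traits, and the
  reason the data-stream null is preferred wherever it applies.
- **Recovery**: Louvain ARI ≥ 0.7 and K within ±2 at the strong-signal
  defaults; differentiation bias ≤ 0.15 at CV 0.8, d = 20 over 50
  replicates; residency decay constant within 15% on a staggered-arrival
  emigration study (synchronized arrivals are a known degenerate case — the
  estimator's day-pair normalization cancels the decay).
- **Power**: 100 replicates of a 4-community study whose position means are
  ~3 within-community SD apart and bubble-net rates span 0.05–0.6; forward
  congruency and reverse randomization must each reject in ≥ 80%.

Study sizes were chosen so the full suite runs comfortably on one CPU while
keeping every rate estimate's Monte-Carlo error well inside the bands it is
checked against.

## Known limitations

- The geographic-overlap predictor uses year-level mean positions; an
  encounter-level variant would be stricter but is not what the yearly
  overlap definition describes.
- The gregariousness floor makes dyads of near-isolated individuals extreme
  leverage points in the GAI regression; such dyads are better interpreted
  through their raw SRI.
- Data-stream permutation is a Markov chain; with very few groups per day
  its effective randomization is limited (a warning reports swap shortfalls).
- The Poisson approximation in the differentiation likelihood overstates
  sampling variance slightly when true indices are large (> 0.5), biasing S
  downward a few percent in that regime.
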