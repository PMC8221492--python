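# whalesoc

Social network analysis of photo-identification sighting records, built for
long-term cetacean studies in which the question is not just *who associates
with whom* but whether the social structure of a population lines up with how
its members use habitat — *social niche partitioning*. The motivating system
is a humpback whale feeding aggregation in a fjord system, observed over many
annual field seasons, where group bubble-net feeding, residency timing, and
position along the fjord axis all appear to organize along social boundaries.

## What it computes

From a CSV of photo-ID events (date, individual, group, position, behaviors),
the pipeline derives:

- **Capture histories and summaries** — sampling occasions are calendar days;
  encounters are unique groups per day; annual identification/recapture
  tables and cumulative recapture distributions.
- **Site fidelity** — Lagged Identification Rates
  `LIR(τ) = Σ m(t, t+τ) / Σ n(t) n(t+τ)` with bootstrap CIs, a
  random-movement permutation null, and exponential decay-model fits
  (closed; emigration `R = e^(−τ/a)/N`; emigration + reimmigration
  `R = (b + (1−b) e^(−τ/a))/N`); occurrence/permanence/periodicity and the
  standardized site-fidelity index `SSFI = 2 / (1/I_T + 1/I_t)`.
- **Associations** — the Simple Ratio Index
  `SRI = x / (x + y_A + y_B + y_AB)`, data-stream permutations (within-day
  group swaps preserving group sizes and daily presence), Lagged Association
  Rates with social-process decay fits, and maximum-likelihood social
  differentiation `S` (CV of the latent true association indices under a
  Beta mixing model with Poisson sampling).
- **Affiliations** — Generalized Affiliation Indices: signed deviance
  residuals of a binomial regression of dyadic association counts on joint
  gregariousness, geographic overlap, and temporal overlap; subnetwork
  preference tests against the data-stream null.
- **Network structure** — Louvain communities with modularity nulls and a
  multi-year running-window stability series.
- **Niche congruency** — k-means clustering of standardized habitat-use
  traits (k pinned to the social community count), Adjusted Rand Index
  congruency with forward (label-shuffle) and reverse (trait-shuffle +
  re-cluster) randomizations, exhaustive variable-subset sweeps, and the
  dyadic behavior-transference bootstrap test.
- **Assortativity and positions** — weighted assortativity coefficients on
  positive- and negative-affiliation networks with node-shuffle nulls;
  generalized weighted betweenness (edge cost `(1/w)^α`, α = 0.5), harmonic
  closeness, clustering; node-permutation regressions of position on traits.
- **Synthetic data** — a seedable generator that plants social communities
  with community-linked residency, arrival, position, and behavior, so every
  stage above can be validated end to end against known truth.

## Worked example

```python
import whalesoc as ws

# a five-season synthetic study with 7 planted communities
records, truth = ws.simulate(ws.SimConfig(seed=1))
encounters = ws.build_encounters(records)
history = ws.build_capture_history(encounters=encounters)

dyads = ws.sri_matrix(history, min_sightings=5)
part = ws.detect_communities(ws.build_network(dyads), seed=1)
print(f"{part.k} communities, modularity {part.modularity:.3f}")

traits = ws.trait_table(encounters, history).loc[dyads.ids]
cluster = ws.trait_kmeans(traits, ["bubble_net_rate", "mean_position"],
                          k=part.k, seed=1)
res = ws.congruency_test(part.as_series(), cluster, n_iter=1000, rng=1)
print(f"congruency ARI {res.ari:.3f}, p = {res.p_value:.4f}")
```

prints

```
7 communities, modularity 0.254
congruency ARI 0.329, p = 0.0010
```

Seven communities are recovered from the simulated association network; the
behavioral clustering agrees with the social partition far beyond chance
(the label-shuffle null ARI is centered on zero), which is the planted
social niche partitioning being detected. On real data of this size and
sparsity, congruency ARIs are typically far smaller yet still significant —
the p-value against the null distribution, not the raw ARI, carries the
inference.

A thin CLI covers the common stages
(`whalesoc simulate|summary|lir|sri|communities|congruency`).

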