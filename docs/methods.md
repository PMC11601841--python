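# Methods

## Model

One model is fit per (site, outcome, stratum) query. Cells are indexed by
area $i = 1..I$, age group $a = 1..A$ and year $t = 1..T$; events within a
queried "all" stratum (e.g. both sexes) are aggregated by summing events
and person-years before fitting. Cells with zero person-years contribute
nothing to the likelihood.

$$y_{iat} \sim \text{Poisson}(n_{iat}\lambda_{iat}), \qquad
\log\lambda_{iat} = \mu + \alpha_a + u_i + v_i + \gamma_t$$

The convolution prior splits area-level heterogeneity into a spatially
structured part $u$ (intrinsic CAR on the area adjacency graph, improper,
rank-deficient by one per connected component) and an exchangeable part
$v_i \sim N(0, 1/\tau_v)$. The year effect $\gamma$ is a first-order random
walk. For year-range queries, years are collapsed by summing and the
temporal term is dropped ($T = 1$).

Identifiability: the ICAR and RW1 priors are invariant to level shifts, so
$u$ (per component), $\gamma$ and $\alpha$ are constrained to sum to zero
and $\mu$ carries the overall level. The constraints are enforced by
re-centering after each block sweep with the subtracted mean absorbed into
$\mu$; on a connected graph this leaves the likelihood untouched (and the
$N(0,10^2)$ prior on $\mu$ is flat enough that the density perturbation is
negligible — the standard disease-mapping device). On a graph with several
components the per-component means are absorbed through their area-weighted
average; the residual per-area shift is the difference between a
component's mean and the overall mean, which is small when components are
balanced. Archipelago geographies are accepted but interpreted with that
caveat.

Hyperpriors are $\text{Gamma}(1, 0.01)$ on all three precisions — proper
and weakly informative, which keeps the posterior proper despite the
improper ICAR — and $N(0, 10^2)$ on $\mu$ and $\alpha$.

## Sampler

Adaptive component-wise Gaussian random-walk Metropolis for $\mu$, each
$\alpha_a$, $u_i$, $v_i$, $\gamma_t$, plus conjugate Gibbs draws for the
precisions:

* $\tau_u \sim \text{Gamma}\big(a_0 + (I - C)/2,\; b_0 + \tfrac12\sum_{i\sim j}(u_i - u_j)^2\big)$
  with $C$ the number of graph components (the ICAR rank deficiency);
* $\tau_v \sim \text{Gamma}(a_0 + I/2,\; b_0 + \tfrac12\sum v_i^2)$;
* $\tau_g \sim \text{Gamma}\big(a_0 + (T-1)/2,\; b_0 + \tfrac12\sum(\gamma_t - \gamma_{t-1})^2\big)$.

Proposal SDs start at 0.1 and adapt per parameter in batches of 50
burn-in iterations toward 0.44 acceptance (the scalar-target optimum), with
step size $\min(0.05, m^{-1/2})$ at batch $m$; adaptation freezes at the
end of burn-in, so the retained draws come from a fixed, valid kernel.

Defaults: 2 chains, 11,000 iterations, 1,000 burn-in, thin 10 — 2,000
retained draws. Chains are initialized at the crude overall log-rate with
all effects zero. Convergence is monitored by classic split-chain
Gelman–Rubin $\hat R$ on $\mu$, the precisions and three randomly chosen
$u_i$; the CLI fails a fit whose worst monitored $\hat R$ exceeds 1.2.

Performance: the Poisson expectation factorizes as
$n_{iat}e^{\mu}e^{\alpha_a}e^{u_i+v_i}e^{\gamma_t}$, so each single-site
update needs only cached contractions of the exposure tensor
($nG = \sum_t n\,e^{\gamma}$, $nA = \sum_a n\,e^{\alpha}$,
$S = \sum_{a,t} n\,e^{\alpha}e^{\gamma}$), updated incrementally on
acceptance. A full default fit of 100 areas runs in tens of seconds on one
CPU.

Determinism: all randomness flows from one integer seed through named
CRC-32-keyed `SeedSequence` substreams (chain $c$ uses
`stream(seed, "chain", c)`). Inside the sampler every per-area loop and
every cross-area reduction runs in a canonical order (areas sorted by id),
so permuting the storage order of areas permutes the posterior draws
bit-exactly — a property the suite checks.

## Derived measures

* **Age-adjusted rate**: $R_i^{(m)} = 10^5\sum_a w_a \exp(\mu^{(m)} +
  \alpha_a^{(m)} + u_i^{(m)} + v_i^{(m)} + \gamma_{t^*}^{(m)})$ at the
  queried year $t^*$ (omitted for year-collapsed fits). Point estimate =
  posterior mean; interval = equal-tailed 2.5/97.5 percentiles. The
  standard population is a configurable weight vector; the synthetic
  fixture uses flat weights (0.25 × 4); for real use the US 2000 standard
  is the documented choice.
* **State reference**: per draw, the person-years-weighted mean of area
  age-specific rates, then standardized with the same weights — so the
  reference matches the observable state rate in expectation.
* **Risk probability**: fraction of draws with $R_i^{(m)} > R_{\text{state}}^{(m)}$;
  ties count as not exceeding (conservative). Being a per-draw rank
  statistic it is invariant to monotone transforms applied to both series.
* **Hotspots**: the top $\lceil fN \rceil$ areas by point estimate
  ($f = 0.10$ by default); ties at the threshold rate are all flagged.
* **Uncertainty classes**: tertile split of the posterior rate SDs at the
  1/3 and 2/3 empirical quantiles; an SD equal to a break goes to the
  lower class; fewer than 3 areas degenerate to "low" with a warning.
* **Suppression**: the raw direct rate is reported only when the total
  event count reaches the threshold (default 16, a common registry
  convention; boundary inclusive); otherwise it is marked suppressed and
  the modeled estimate stands in.

## Geography

Adjacency comes from polygon contiguity (queen rule by default — shared
boundary point; rook requires a shared segment of positive length), from an
explicit edge list, or from the synthetic lattice generator. Coordinates
are assumed planar; only topology is used. Disconnected graphs are allowed;
spatial constraints apply per component.

Choropleth class breaks are quantile (linear-interpolation quantiles at
$i/k$) or equal-interval; with fewer distinct values than classes the
quantile method falls back to equal-interval, and constant input collapses
to a single class. A value equal to a break belongs to the lower class, so
classes are left-open/right-closed intervals $(b_{j-1}, b_j]$; this is the
convention the exports embed and the one round-trip tests pin down. Six
colorblind-friendly ColorBrewer ramps (YlGnBu, YlOrRd, GnBu, BuPu, PuOr,
BrBG) are available; hex values are config data.

## Synthetic registry

The generator is first-class, tested code — it defines the study
conditions for every model-level claim the suite makes.

* Truth surface: spatial effect drawn from the ICAR distribution via the
  eigen-structure of the graph Laplacian, centered per component and
  rescaled so the average theoretical marginal SD equals the requested
  value (default 0.3 on the log scale — moderate geographic heterogeneity);
  temporal effect a centered random walk (SD 0.05/year); age baselines
  20/60/200/600 per 100,000 person-years across four age groups (the steep
  age gradient typical of adult solid tumours); additive sex and
  race offsets of ±0.1–0.25 on the log scale.
* Populations: per-area annual person-years log-uniform on [500, 50,000]
  (registry area sizes are strongly right-skewed), split by configured age
  (0.35/0.25/0.25/0.15), sex (0.5/0.5) and race (0.85/0.15) shares,
  constant over years unless a drift is configured.
* Counts: incidence is Poisson against the truth surface; late-stage is
  binomial thinning of incidence (fraction 0.35); mortality is Poisson at
  0.4 × the incidence rate. An optional mean-one lognormal overdispersion
  multiplier mis-specifies the Poisson assumption for robustness tests.

Because the generating family equals the fitted family, recovery and
coverage tests are well-posed — and deliberately favorable. What they do
not show: robustness to real registries' non-Poisson overdispersion beyond
the provided switch, geocoding error, population denominator error,
in-migration, or age structures that differ sharply between areas.

## Problem sizes used in the suite

The standard fixture is a 10×10 queen lattice, 4 age groups, 2 sexes, 2
race labels, 5 years — about 3,800 events across 100 areas for the
incidence query — fit at the default 2 × 11,000 iterations. Smaller
lattices (2×2 to 5×5) and shorter chains back the kernel-level checks
(detailed balance against a grid-normalized full conditional at 50,000
sweeps, permutation equivariance, conjugate single-area limit against a
Gamma oracle).

## Known limitations

* No space-time interaction term and no covariates (ecological
  regression); strata are fit separately with no cross-stratum pooling.
* The state reference is the person-years-weighted aggregate of the
  modeled rates, not an independently fitted state model.
* Re-centering on multi-component graphs is approximate (see above).
* Population density is not computable (no area measurements); the
  searchable size measure is total person-years.
* PNG map rendering is out of scope; the GeoJSON + style metadata is the
  canonical map deliverable.
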