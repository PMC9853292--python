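# Methods

This note defines the statistical procedures implemented in `menpipe`, the
parameters they expose, and the design of the synthetic community generator
used to validate them.

## 1. Preprocessing

**Rarefaction.** Each sample is subsampled *without replacement* to a fixed
depth via the multivariate hypergeometric distribution
(`numpy.random.Generator.multivariate_hypergeometric`, marginals method).
Samples below the depth are dropped with a warning; OTUs left with all-zero
rows are removed. Default depths follow the emulated wetland survey design:
50,000 reads (prokaryotes), 51,591 (fungi), 33,548 (cercozoa).

**Prevalence filter.** Before network construction, OTUs must be present
(count > 0) in *strictly more than* `min_prevalence` of samples (default
0.8, a "shared by more than 80% of samples" rule). This removes sparse
profiles whose rank correlations are dominated by tied zeros.

**Alpha diversity.** Shannon H in nats; Pielou evenness H/ln S (undefined
for S ≤ 1); bias-corrected Chao1 = S + F₁(F₁−1)/(2(F₂+1)) with F₁
singletons and F₂ doubletons; observed richness.

**Guilds and groups.** Methanogens and methanotrophs are recognized by
taxonomy substrings (the classical euryarchaeotal methanogen orders plus
Methanocellales and Methanomassiliicoccales; pmoA-bearing aerobic
methanotroph orders), first match wins. Inundation depths map to three
groups: IL (control, 0 cm), IM (5/10/20 cm), IH (30/40 cm); the demo design
has 7/12/8 samples per group.

## 2. Association networks and RMT threshold selection

Pairwise Spearman ρ is computed over OTU relative-abundance profiles
(average ranks for ties; ranks are invariant to the compositional closure,
so this equals Spearman on counts whenever sample depths are equal).
Zero-variance profiles get ρ = 0 with a warning. An edge joins two OTUs when
|ρ| ≥ s; edges keep the signed ρ as weight; isolated nodes are dropped.

**Threshold choice.** Two modes:

- *fixed*: a per-community map of cutoffs. The study-derived values
  (0.960 / 0.840 / 0.890 per kingdom, 0.85 interdomain) are exported as
  `STUDY_FIXED_THRESHOLDS`. The demo default uses 0.85 for every community:
  with planted within-module ρ = 0.9 observed at 27 samples, the sampling
  distribution of empirical ρ tops out near 0.93, so a 0.96 cutoff would be
  infeasible by construction on data of this size.
- *rmt*: scan s from 0.30 to 0.99 in steps of 0.01. At each s, zero entries
  with |ρ| < s (keeping signs, unit diagonal), take eigenvalues, and test
  the unfolded nearest-neighbour spacing distribution (NNSD). The selected
  threshold is the smallest s whose NNSD is *not* rejected against the
  Poisson law e^(−d) at α = 0.05; below the transition, dense noise
  correlations produce Gaussian-orthogonal-ensemble (GOE) spacings
  (Wigner surmise (π d/2)e^(−π d²/4), level repulsion).

**Unfolding.** Degenerate eigenvalues (within 10⁻⁸) are collapsed; spectra
with fewer than 20 distinct eigenvalues are skipped as degenerate. The
cumulative spectral function is fit with a monotone piecewise-cubic
interpolant (PCHIP) through every 8th eigenvalue with exact endpoints, so
unfolded spacings are non-negative with mean exactly 1. A cubic *smoothing*
spline was tried first and rejected: it is not monotone and violated the
mean-spacing ≈ 1 invariant (observed 1.064). The knot spacing of 8 is a
method constant chosen to track the secular spectral density without
whitening genuine spacing fluctuations; behavior is stable for spacings
6–9.

**Goodness of fit.** χ² with histogram bin width 0.1 on [0, 3] (upper tail
clipped into the last bin). Because realistic spectra yield only ~50–200
spacings, adjacent bins are pooled until each expected count reaches 5
(Cochran's rule); df = pooled bins − 1. Without pooling the χ²
approximation spuriously rejects everything.

**Interdomain network.** Kingdom tables are merged on their shared samples
after per-kingdom prevalence filtering; node categories are
methanogen / methanotroph (from guild annotation) or otherwise the kingdom,
so categories partition the node set.

## 3. Topology, vulnerability, robustness

All metrics are unweighted. Global efficiency
E = mean over ordered pairs of 1/d(i,j) (0 for disconnected pairs).
Vulnerability V = maxᵢ (E − Eᵢ)/E, Eᵢ the efficiency after deleting node i
(renormalized over N−1 nodes); closed forms: complete graph 0, star 1,
path P₃ 1. Average path distance averages over *connected* pairs only;
average clustering counts degree-<2 nodes as 0.

Robustness removes ⌊fN⌋ nodes (uniformly at random, or module hubs first,
padded with random non-hubs), then applies secondary extinction — nodes
left with zero links are also considered lost — and reports the mean
surviving fraction over replicates (or over every removal set in exhaustive
mode). One extinction pass suffices: removing an isolated node cannot
isolate anyone else.

## 4. Modules, roles, eigengenes

Modules are detected by fast-greedy (Clauset–Newman–Moore) modularity
optimization on the unweighted, unsigned graph; module ids are ordered by
size descending (ties by smallest node id), so partitions are deterministic.

Node roles use the standard keystone plane: Zi is the within-module degree
z-score (population sd per module, so Zi has mean 0 and sd 1 within each
module; Zi = 0 when the module has no degree spread), Pi = 1 − Σₜ(k_it/k_i)²
over modules t. Module hubs Zi > 0.25, connectors Pi > 0.62, network hubs
both, boundaries excluded.

The module eigengene is the leading right singular vector (sample space) of
the module's row-standardized (ddof = 1) relative-abundance matrix, with
sign fixed so it correlates non-negatively with the module's mean
standardized profile; explained variance = σ₁²/Σσ². Constant profiles are
excluded; modules with fewer than two usable profiles have no eigengene.
Eigengene–trait associations are Pearson r with two-sided t-test p and the
printed star convention (\*, \*\*, \*\*\* at 0.05/0.01/0.001), optionally
with Benjamini–Hochberg adjustment.

## 5. Community statistics

Jaccard distances are binary (presence/absence after rarefaction). The
Mantel test correlates the off-diagonal triangles (Pearson), permuting one
matrix's labels jointly over rows and columns; p is one-sided upper-tail
with the +1 correction, p = (1 + #{r* ≥ r})/(1 + permutations). An exact
mode enumerates all n! permutations (identity included; p = #{r* ≥ r}/n!),
used for small-n verification. Trait vectors enter as Euclidean distances
on the standardized trait. MRPP (weighted mean within-group distance δ,
effect A = 1 − δ/mean δ*, lower tail), ANOSIM (rank-based R, upper tail)
and PERMANOVA (pseudo-F on squared distances, upper tail) share one seeded
label-shuffling null. Constant distance matrices are reported as missing
rather than fabricating p-values. PCA runs on centered relative abundances;
ANOVA is the classical one-way F; flux regressions are ordinary least
squares with R² and the slope t-test p.

With 199 permutations the rejection rule p ≤ 0.05 is exact at level
10/200 = 0.05 under exchangeability; the acceptance suite verifies the
empirical rejection rate over 200 null simulations for all four tests.

## 6. Synthetic community generator

The generator produces data with *known* answers for every analysis stage:

- **Pool.** 120 prokaryote, 40 fungus, 40 cercozoa OTUs. Four modules of 20
  OTUs are planted by interleaving kingdoms by fractional rank, so every
  module spans all three kingdoms. 10% of prokaryotes are labelled
  methanogens and 5% methanotrophs, with taxonomy strings embedding real
  order names so the guild annotation recovers them.
- **Correlation.** Target Spearman ρ_w = 0.9 within modules, 0 elsewhere.
  A Gaussian copula converts the target to the latent Pearson scale
  (r = 2 sin(πρ/6)); correlated normals are exponentiated to log-normal
  relative abundances and each sample is multinomially resampled to its
  exact sequencing depth — a compositional count model.
- **Rank abundance.** Per-OTU log-means are Normal(0, σ) with a two-tier σ:
  planted module members use σ = 1, background OTUs σ = 2. Rationale: any
  OTU surviving an 80% prevalence filter is by definition part of the common
  core, and a planted module whose members fall below one read per sample
  would be unobservable in principle; the wider background tier supplies
  the realistic rare tail whose presence/absence variation drives the
  Jaccard-based statistics. (A single σ cannot satisfy both requirements at
  these depths: σ = 1 makes every OTU omnipresent and all Jaccard distances
  equal, σ = 2 everywhere makes a fraction of the planted members too rare
  to correlate reliably at 27 samples.)
- **Metadata.** Three inundation groups (7/12/8), eight environmental
  variables with group shifts in the directions reported for inundated
  wetland soils (pH, oxygen, nitrate depressed), and CH₄ flux defined as
  β·(module-1 eigengene) + Normal(0, noise_sd·sd(eigengene)); the
  population flux–eigengene correlation is β/√(β² + noise_sd²) = 0.8 at
  the defaults (β = 1, noise_sd = 0.75). The eigengene is computed by the
  same `module_eigengene` operation the analysis uses, so there is a single
  definition. Gene copy numbers (mcrA, pmoA) are log-normal around 10⁷
  copies/g, weakly tracking flux.

**What the generator does not emulate:** real phylogenetic correlation
structure, thousands-of-OTU richness, sequencing error, or overdispersion
beyond the multinomial; the planted truth is block-structured rather than
scale-free. It is a test harness for the statistical machinery, not a soil
microbiome simulator.

## 7. Determinism and problem sizes

Every stochastic stage receives a child seed derived from the run seed and
the stage name via `SeedSequence([seed, crc32(stage)])` (kept below 2³¹),
so reruns are byte-identical and stages are individually reproducible. The
demo problem (200 OTUs, 27 samples) completes in a few seconds; the
per-node efficiency loops use `scipy.sparse.csgraph` shortest paths and
remain practical to a few hundred network nodes, which covers
prevalence-filtered amplicon networks.
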