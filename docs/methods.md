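# Methods

This note documents the models implemented in `brackish`, the conventions
chosen where the field leaves room, what the synthetic-data generator does
and does not emulate, and the package's known limitations. Nothing here is
an empirical claim beyond what the test suite and `scripts/acceptance.py`
themselves compute.

## Data model and partitions

An `OtuTable` is a non-negative integer matrix of reads, samples × OTUs.
Occupancy is `count > 0` — no minimum count is required for an OTU to
"count as present" in a sample. Rare-OTU filtering removes an OTU when its
occupancy is below `min_samples` **and** its total reads are below
`min_total_reads` (defaults 5 / 10; 20 / 200 before network construction).
The conjunctive reading is deliberate: it is the weaker filter, so no OTU
that either condition alone would keep is silently lost; a `disjunctive`
mode is available.

Rarefaction draws each sample down to a fixed depth *without replacement*
(multivariate hypergeometric); samples below the target depth are dropped
with a logged warning rather than padded. Occupancy classes are computed on
the rarefied analysis table: core ≥ 75 % occupancy, satellite < 50 %,
intermediate otherwise.

Salinity levels partition samples at breaks (0.2, 2.0) ‰ with right-closed
intervals — [0, 0.2], (0.2, 2], (2, ∞) — so a sample at exactly 0.2 ‰ is
"low". The printed ranges in the field overlap at the endpoints, so some
convention is required; both breaks and closure are configurable.

## Diversity and permutation statistics

Alpha indices follow the vegan conventions: Shannon H = −Σ p ln p (nats),
Simpson reported as the Gini–Simpson complement 1 − Σ p² (larger = more
diverse; the dominance form is a flag away), Pielou J = H / ln S_obs,
Chao1 = S_obs + F1²/(2 F2) with the bias-corrected form used only when
F2 = 0, and ACE with the standard rare/abundant cutoff of 10. Bray–Curtis
distances are computed on relative abundances by default.

ANOSIM uses Clarke's statistic R = (r̄_between − r̄_within) / (M/2) with
M = n(n−1)/2 (identical to vegan and scikit-bio; verified against
scikit-bio numerically in the tests). Mantel statistics correlate
off-diagonal entries (Pearson or Spearman); p-values permute one matrix's
rows and columns simultaneously, one-sided with the +1 correction. The
partial Mantel r_AB·C uses the first-order partial-correlation formula and
permutes the community matrix (dA) following Legendre; for n ≤ 8 an exact
full-enumeration Mantel p is available and the sampled p agrees with it to
< 0.02 (asserted in the acceptance suite).

Time-lag regression pairs every two samples and correlates (Spearman)
their Bray–Curtis dissimilarity with the time lag. Two lag types are
offered: absolute |Δt| in days, and an annual-cycle lag in months where
day differences are mapped to fractional months (Δdays / 30.44) and folded
so that January vs December is 1 month, January vs July 6.

The multi-nutrient cycling index is the averaging form of
multifunctionality: the mean of per-variable z-scores across the nutrient
variables (default TC, TOC, TN, NH4-N, NO3-N, NO2-N, TP, PO4-P); constant
variables are excluded with a warning. This averaging z-score form is a
declared convention and is labelled as such in output metadata.

## Neutral community model

Sloan's model predicts the occurrence frequency of a taxon with mean
relative abundance p in communities of size N with migration probability m
as

    freq(p) = 1 − I_d(N·m·p, N·m·(1 − p)),   d = 1/N,

where I is the regularised incomplete beta function and d the detection
limit. `fit_ncm` estimates the single free parameter Nm by unweighted
non-linear least squares over OTUs (bounded search on log10 Nm ∈ [−3, 9];
estimates at the boundary, or tables whose occupancies have no variance,
are flagged). N defaults to the median sample depth, exact for rarefied
tables, and m is reported as Nm/N. Goodness of fit is Östman's
R² = 1 − SS_res/SS_tot; the 95 % envelope is the Wilson binomial interval
around the predicted frequency at n = number of samples, and OTUs are
partitioned into above/within/below the envelope.

Known limitation (quantified during development): presence in real count
data is `count ≥ 1`, whose probability 1 − (1−x)^N is a smoothed,
left-shifted version of the model's step at d = 1/N. Fitting the
threshold-form model to binomially sampled data therefore inflates Nm by
roughly 15–30 %, the more so the larger m and the more taxa sit near the
detection limit. Under the generator's default species-abundance
distribution (log-normal, σ = 1.0) the recovered m stays within ±25 % of
truth across m ∈ {0.05, 0.1, 0.3} (asserted in the acceptance suite);
heavier-tailed pools (σ ≥ 1.5) can push the bias past that band at
m = 0.3.

## Niche breadth

Levins' B_j = 1/Σ_i P_ij², with P_ij the share of taxon j's **own** total
abundance found in sample i (within-taxon normalisation). This choice
makes B_j span [1, N]: 1 for a taxon confined to one sample, N for one
spread evenly over N samples, matching the generalist/specialist
semantics. The community value Bcom is the unweighted mean of B over the
taxa present in a sample. The alternative within-sample normalisation
would not have these bounds.

## C-score null model

The Stone–Roberts C-score is the mean over species pairs of
(R_i − S_ij)(R_j − S_ij) on the presence/absence matrix (species as rows).
The null model fixes both row and column sums and is sampled by a
sequential-swap Markov chain: each step proposes a uniformly random 2×2
submatrix and swaps it iff it is a checkerboard. Because the proposal is
symmetric and a step is an *attempt* (failed proposals count as steps),
the stationary distribution is exactly uniform over all matrices with the
given marginals; on 4×4 instances the sampled null matches complete
enumeration with KS < 0.01. Defaults: 30 000 null samples, burn-in of
5× the matrix fill, thinning 1 attempt; all configurable. SES =
(C_obs − mean_null)/sd_null, with |SES| > 2 read as non-random structure
(positive = segregation). Empirical tail probabilities carry the +1
correction and a normal-approximation p is reported alongside.

The C-score bookkeeping is incremental — a swap touches two rows, so the
shared-site matrix and the pair-sum are updated in O(S) — which is what
makes tens of thousands of null samples cheap.

## SparCC

Relative abundances are compositional, so Pearson correlations between
them are biased; SparCC instead estimates basis correlations. Per inner
iteration (default 20): fractions are Dirichlet-resampled per sample with
a pseudocount of 1 on every count; the log-ratio variance matrix
T_uv = var(log x_u − log x_v) is formed from the log-fraction covariance;
basis variances ω solve the linear system t = M ω implied by the sparsity
assumption (M = J + (S−2)I); and the strongest pair with |ρ| above the
exclusion threshold (0.8) is iteratively removed from the system (up to 10
rounds). Correlations are averaged over iterations and clipped to [−1, 1].
Each sample's resampling stream is keyed by its id, so the estimate is
invariant to sample order.

P-values are two-sided empirical: each of n_boot (default 100) replicates
permutes every OTU column independently — destroying inter-OTU dependence
while preserving marginals — re-runs SparCC (5 inner iterations by
default for the null), and counts |r_null| ≥ |r_obs| per pair, with the
+1 correction (floor 1/(n_boot+1); at 100 permutations the floor 0.0099
clears the p < 0.01 edge threshold). A bootstrap option was considered and
rejected in favour of the permutation null, which has the cleaner
uniformity guarantee under independence.

Networks keep an edge where |r| > 0.6 **and** p < 0.01 (strict
inequalities); isolated nodes are dropped by default. Topology and
robustness treat the network as unweighted — natural connectivity and the
node-removal procedure operate on adjacency structure — while the signed
r and p are retained on every edge for reporting and export (edge-list
TSV, GraphML).

## Topology, modules, roles

The topology summary reports mean local clustering, average shortest path
length on the largest connected component (with the component's node
coverage, since the full-graph quantity is undefined when disconnected),
and the modularity of the detected partition. Module detection defaults to
greedy modularity (deterministic) with seeded Louvain as an option. The
degree-distribution verdict fits a discrete power law (zeta-normalised
MLE over the observed support) against a Poisson MLE and compares by AIC
(both one-parameter, so by log-likelihood); a log–log regression R² on the
degree histogram is reported alongside. On synthetic inputs the verdict
separates Barabási–Albert from Erdős–Rényi graphs in ≥ 9/10 seeds.

Erdős–Rényi null ensembles use G(n, M) — exactly the observed node and
edge counts, edges placed uniformly — with per-metric mean, sd and the
empirical quantile of the observed value (default 1000 graphs).

Node roles follow Guimerà–Amaral: Zi is the z-score of a node's
within-module degree against its module (0 where the module sd is 0), Pi
= 1 − Σ_s (k_is/k_i)²; thresholds (2.5, 0.62) classify network hubs,
module hubs, connectors and peripherals, and all non-peripherals are
candidate keystones. Degree-0 nodes are flagged peripheral with Pi = 0.

βw between two networks compares edge sets as unordered id pairs:
βw = (a+b+c)/((2a+b+c)/2) − 1, i.e. 0 for identical and 1 for disjoint
non-empty edge sets.

Natural connectivity is ln((1/n) Σ_i e^{λ_i}) over the adjacency
eigenvalues (computed with `logsumexp` for stability); the robustness
curve removes a fraction of nodes uniformly at random (grid 0–0.8 by 0.05,
100 repetitions) and reports mean ± sd of the remaining graph's natural
connectivity, with the fraction-0 value exactly the intact one.

## Synthetic data: what it does and does not emulate

The generator draws each sample's per-taxon relative abundances from the
Sloan stationary Beta(N·m·p_j, N·m·(1−p_j)) marginal and then N reads
multinomially — exactly the distribution the NCM fitter assumes, which is
what makes parameter recovery a clean oracle. Independent per-taxon Beta
draws are renormalised before the multinomial (compositional closure
accepted; the bias is negligible at S ≥ 100). Salinity selection
multiplies the source pool by Gaussian niche factors
exp(−strength·(s − optimum_j)²/(2σ²)) before sampling; strength 0 is
bit-identical to the neutral path under the same seed. Implanted
correlations act on latent log-normal basis abundances before closure
(shared factor per pair, λ² = |ρ|·σ_log²), because SparCC infers basis
correlations; rows are then redrawn multinomially at their original depth.
Metadata emulate a twice-weekly, 13-month campaign with a seasonal
salinity profile anti-correlated with generated precipitation.

Not emulated: sequence-level error, chimeras or taxonomy (no FASTQ),
phylogenetic structure, temporal autocorrelation of community composition
beyond what salinity tracking induces, and OTU-level temporal succession.
Passing tests therefore demonstrate estimator correctness under the
models' own assumptions, not robustness to upstream bioinformatic noise.

## Problem sizes and numerical choices

Simulation-based checks run at scaled sizes chosen to exercise the
asymptotics that matter while staying cheap: parameter recovery at S = 300
taxa, 120 samples, 5000 reads; selection-direction pairs at S = 200, 60
samples, 2000 reads, strength 6, with 3000-sample swap nulls; SES
calibration on 20×50 incidence matrices at 30 % fill with 3000 null
samples thinned by 10; Mantel calibration on 15-sample matrices with 199
permutations; SparCC recovery at 50 OTUs × 120 samples with 100
permutation replicates. Defaults shipped in `PipelineConfig` are the
full-scale analysis constants (999 permutations, 30 000 swap samples,
1000 random graphs, rarefaction depth 146 973), not these test sizes.

Ties and degeneracies: zero-variance modules give Zi = 0; all-zero samples
are rejected by Bray–Curtis; OTUs absent everywhere are excluded from
niche breadth and the NCM with warnings; a swap-degenerate incidence
matrix (no checkerboard) is returned unchanged with a warning by
`sequential_swap` and is an error for SES; permutation p-values never fall
below 1/(n_perm+1). All randomness flows through explicit integer seeds;
the pipeline expands one root seed per stage through a stable hash so that
editing one stage never perturbs another's draws, and a repeated run is
checksum-identical.
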