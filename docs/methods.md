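# Methods

## Scope and model

The package studies one quantity, the degree-resolved clustering
coefficient C(k) = mean over degree-k nodes of 2N/(k(k−1)), and asks
which structural features are sufficient to make it fall as k⁻¹.
Three mechanisms are implemented and can be disentangled against each
other: recursive hierarchy (the deterministic 5-clique model),
super-hubs (single nodes far above the power-law structural cutoff),
and generic hub–hub repulsion (negative degree correlations).

Clustering is undefined for nodes of degree 0 or 1 (the denominator
k(k−1) vanishes), so such nodes are excluded from every clustering
statistic, including the mean clustering C̄. C(k) is always computed
per exact degree; logarithmic (base-2) binning is a presentation and
fitting device only, and binned means are node-count-weighted with a
geometric-mean bin degree.

## Deterministic hierarchical model

Level 1 is a 5-clique with one center and four peripheral nodes. At
level L, four replicas of the level-(L−1) module are made and each
replica's 4^(L−1) bottom-level peripheral nodes (recursively, the
replicas' peripheral sets) are wired to the center of the original
module. This yields 5ᴸ nodes and E(L) = 5E(L−1) + 4ᴸ edges with
E(1) = 10. The construction is exact, so its statistics (node and edge
counts, root clustering 60/380 at L = 2, assortativity −0.0768 at
L = 6) are reproducible to floating point and serve as fixed
reference values in the tests. Levels above 7 are rejected as a size
guard.

## Attachment theory

For a node j of degree k_j wired by preferential attachment into an
uncorrelated graph with S nodes, M edges, mean degree ⟨k⟩ and mean
clustering C̄:

* p_ij = k_i / 2M (attachment probability),
* m_ij = min(k_i k_j / 2M, 1) (expected i–j edge count, capped at one
  by the simple-graph constraint),
* m_j⟨k⟩ = min(k_j ⟨k⟩ / 2M, 1) (same for a typical neighbour),
* ΔN_i = k_i · m_ij · m_j⟨k⟩ (expected new triangles through i),
* C′(k_i) = C̄ + 2ΔN_i / (k_i (k_i + 1)).

While m_ij < 1 the gain is α_j k_i² (α_j = m_j⟨k⟩ k_j / 2M) and C′ is
degree-independent; once m_ij = 1 the gain is α_j k_i and, with C̄ ≈ 0,
C′ ~ 1/k_i. The formulas keep the printed (k_i + 1) denominator — the
degree after the new node has attached.

`required_neighbor_edges(k, cbar)` rounds k(k−1)·C̄/2 to the nearest
integer; it quantifies why a super-hub cannot sustain the network's
mean clustering (at k = 253, C̄ = 0.21 it would need 6,694 neighbour
edges).

## Graph generators

**Configuration model.** Degrees are drawn from the normalized
discrete law P(k) ∝ k^(−γ) on [kmin, kmax], with one entry resampled
until the total is even. The default kmax is the structural cutoff
⌊√(n·kmin)⌋, which keeps the baseline graph free of entropic degree
correlations; injected super-hubs deliberately violate it — that
violation is the object of study. Matching is stub shuffling with
rejection: colliding pairs (self-loops, duplicates) are pooled and
re-shuffled for up to 200 rounds; stubs that remain are dropped with a
warning (in practice ≲ 0.1% of stubs, so ≥ 99% of nodes realize their
requested degree exactly).

**Super-hub injection.** Each injected node of degree d is wired to d
distinct existing nodes drawn without replacement with probability
proportional to their *pre-injection* degree (exponential-race
sampling, which realizes exactly the sequential weighted draw).
Weights are frozen at the input degrees: later hubs see earlier hubs
as zero-weight candidates, so hubs never attach to each other. This is
the simplest defensible convention; the alternative (updating weights
during placement) differs only at second order.

**Spoke model.** n_hubs hubs each get their own leaves; bridge nodes
connect two random distinct hubs. No edge ever joins two hubs, making
the graph disassortative by construction.

## Null models

All nulls preserve node count and edge count exactly; their
constraints tighten in sequence:

1. **Degree-preserving rewiring** (double-edge swaps, via networkx's
   swap routine): preserves every node's degree. Inputs admitting no
   valid swap are returned unchanged with a warning.
2. **Joint-degree seed** (Stanton–Pinar construction, via networkx's
   joint-degree generator): preserves the full joint degree matrix —
   the edge count between every pair of degree classes — and therefore
   the assortativity r exactly, r being a function of that matrix
   alone.
3. **Annealed null**: starts from a joint-degree seed and runs
   Metropolis Monte Carlo on the energy E = |N_random − N_real| /
   N_real (absolute value: the target is a *minimum* of zero, reached
   when the null matches the real triangle count). The proposal picks
   a uniform random edge (a,b) with random orientation, a uniform node
   c from a's exact degree class, and a uniform neighbour d of c, then
   swaps to (a,d),(c,b). Because deg(a) = deg(c), the move provably
   preserves the joint degree matrix; the class-based draw makes every
   proposal constraint-valid, and the proposal is symmetric, so the
   fixed-T chain satisfies detailed balance on the constrained
   ensemble. Degree classes are exact degrees, never bins.

   Schedule defaults: T₀ = 0.05 with geometric cooling ×0.995 every
   10³ steps, at most 2×10⁶ steps, stopping at E ≤ 0.05 (configurable)
   or when the windowed mean energy is stationary (relative change
   < 10⁻³ over 10⁴-step windows). The stationarity stop is gated: it
   only arms once a one-triangle uphill move is accepted < 1% of the
   time (or when T is held fixed), because during cooling the energy
   plateaus transiently at the hot-ensemble equilibrium. The joint
   degree matrix is re-verified against the seed every 10³ steps and
   the energy trajectory is logged at the same cadence. On the
   500-node planted-partition reference fixture the default schedule
   reaches E ≤ 0.05 in ~10⁶ steps (seconds of CPU).

   The chain is an MCMC approximation; no claim of exactly uniform
   sampling over the triangle-constrained ensemble is made. Edges of
   the real network are not forbidden in the null.
4. **Overlapping null**: freezes a uniform random ⌈f·M⌉ of the edges
   (f ≥ 0.3 typically) and applies double-edge swaps to the rest,
   reporting the realized overlap (≥ f, since free swaps can recreate
   original edges).

## Profiles and detection

Correlation profiles compare the joint degree matrix of a graph
against n_random (default 100) rewired counterparts, as a ratio
P/⟨P_r⟩ and a z-score (P − ⟨P_r⟩)/σ_r per log₂ degree-bin pair; raw
degree pairs are too sparse below ~10⁴ nodes. Bins whose ensemble mean
is zero are masked, and calibration statements (e.g. "an ensemble
member is flat against its own ensemble") are evaluated on
*well-sampled* cells with ensemble mean ≥ 5 edges — below that the
ratio and z statistics fluctuate for purely combinatorial reasons,
exactly as in a chi-square validity rule.

Super-hub detection fits a discrete power law by maximum likelihood to
the bulk of the degree histogram — by default degrees from max(kmin, 2)
to the structural cutoff; degree-1 counts are excluded because they
are the part of an empirical distribution most easily distorted (by
sampling floors or by the very hubs under test shifting low degrees
upward). A degree k above the fit range is flagged when the expected
number of nodes of degree ≥ k under the fitted law (Hurwitz-zeta
survival, conditioned on the fit support) falls below α = 0.05. The
fit range and α are exposed because the visual identification the
operation replaces has no canonical threshold.

## Super-hub experiment and slope fitting

The central simulation uses the published conditions: n = 10,000,
γ = 2.6, kmin = 1 (hence kmax = 100), with either 2 injected nodes of
degree 2,000 or 200 of degree 20, and 5 replicate seeds.

Fitted exponents are only meaningful inside a single regime of the
theory, and the crossover at k* = 2M/d is soft: under weighted
sampling without replacement the inclusion probabilities saturate
gradually, reaching 1 only a few-fold above k*. Slope fits therefore
stay a factor 3 away from the crossover: the capped (ΔN ~ k) fit uses
degrees k ≥ 3k*, the uncapped (ΔN ~ k²) fit degrees k ≤ k*/3. For the
degree-2,000 injection k* ≈ 8.5, so the capped fit covers k ≈ 26–100;
for the degree-20 injection k* ≈ 850 exceeds kmax and the whole range
is uncapped. ΔN slopes are ordinary least squares on log₁₀ of the
per-degree mean gains (degrees with zero mean gain drop out of the
log) and are averaged over replicates.

C(k) slopes use log₂-binned, node-weighted means. A single baseline
realization holds only tens of triangles, so the baseline flatness
check pools the per-degree clustering values across all replicates
before binning and fitting; the post-injection C(k) slope is fitted
the same way inside the capped regime, where the 1/k prediction
applies. With these estimators the reference run gives ΔN exponents
≈ 1.03 and ≈ 1.98, post-injection C(k) slope ≈ −0.9, and baseline
slope ≈ 0.15 (flat within noise).

## Co-expression

Arrays missing more than 10% of genes are removed first, then genes
missing in more than 7 remaining arrays (both thresholds exposed —
the absolute 7-array rule is dataset-specific). Correlations are
pairwise-complete Pearson with at least 3 shared observations per
pair, and "larger than 0.65" is read strictly. The units of the
expression values are irrelevant to the operation.

## Synthetic data: what it does and does not show

The generators reproduce the *statistical* features the pipeline is
sensitive to — a power-law bulk with outlier hubs, tunable
assortativity at fixed degrees (greedy target-seeking double swaps),
planted-partition modularity, block-correlated expression with a
shared latent factor per module (value = √ρ·factor + √(1−ρ)·noise,
the simplest mechanism with exact target pairwise correlation). They
do not reproduce the sizes, degree mixtures, or biological annotation
structure of any real dataset; passing tests therefore demonstrate
that the *methods* behave as claimed under controlled conditions, not
that any particular organism's network is or is not hierarchical.

## Numerical conventions

* All stochastic operations take a mandatory integer seed
  (numpy Generator); derived seeds stay below 2³¹.
* Node ids are opaque strings; serialized outputs are sorted
  lexicographically, and experiment reports are byte-identical across
  runs with the same config.
* The joint degree matrix convention follows degree-mixing counts:
  nested dicts count ordered endpoint pairs (diagonal twice the edge
  count); the matrix type stores mirrored unordered counts whose upper
  triangle sums to M.
* Assortativity raises on regular graphs (zero endpoint-degree
  variance) instead of returning NaN; clustering raises on degree < 2.
* Edge-list TSV is the interchange format; GraphML is read-only.

## Known limitations

* The annealer's runtime grows with the triangle deficit of the seed;
  graphs whose joint-degree ensemble cannot reach the real triangle
  count will stop at the stationarity rule with E > tolerance, which
  is reported rather than hidden.
* `joint_degree_seed` requires the input's joint degree matrix to be
  realizable as a simple graph (always true when it came from one).
* Super-hub detection assumes a power-law bulk; histograms far from a
  power law will produce meaningless fits (guarded only by a minimum
  of 10 distinct degrees).
* The overlapping null freezes a *uniform* edge subset; stratified
  freezing (e.g. by degree class) is not implemented.
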