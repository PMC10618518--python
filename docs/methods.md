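# Methods

## Scope and data model

`taphonet` analyses specimen-level records from quadrat excavations of
fossiliferous (typically lacustrine) deposits. The atomic observation
is one specimen with a plot id, taxonomy at up to three levels (order,
family, OTU label), an ordinal preservation grade A–E, a life-stage
flag, and optionally a habitat annotation. All analyses run off two
derived containers: the validated `SpecimenTable` and taxon-by-plot
`AbundanceMatrix` objects at a chosen rank. Specimens that cannot be
labelled at the requested rank are excluded from that matrix but never
dropped from the table; the excluded count is carried as a diagnostic
so identification rates can be reported honestly.

OTU labels ending in the token `(l)` denote immature individuals
(naiads/larvae). Because immatures and adults of the same species often
occupied different habitats and preserve differently, the marker is
kept in the label: the two stages are distinct OTUs throughout, and
grade/composition summaries at coarser ranks append `(l)` to keep the
groups separate.

## Richness estimation and rarefaction

Observed richness S_obs understates diversity when a few aquatic taxa
are hyper-abundant and the terrestrial tail is rare, so the package
implements the two standard nonparametric estimators.

* **Chao1** = S_obs + F₁(F₁−1)/(2F₂), with F_i the number of OTUs seen
  exactly i times. When F₂ = 0 this divides by zero; we use the
  standard bias-corrected variant S_obs + F₁(F₁−1)/(2(F₂+1)), which
  keeps the estimate finite and ≥ S_obs in all cases.
* **ACE** splits OTUs at a rare-abundance threshold (default 10
  individuals; configurable, because fossil assemblages may warrant a
  lower one). With S_rare, N_rare the rare-group richness and
  abundance, sample coverage C_ACE = 1 − F₁/N_rare, and
  γ²_ACE = max[(S_rare/C_ACE)·Σᵢ i(i−1)Fᵢ / (N_rare(N_rare−1)) − 1, 0]
  (the sum running up to the threshold), the estimate is
  S_abund + S_rare/C_ACE + (F₁/C_ACE)·γ²_ACE. Degenerate rare groups
  (S_rare = 0, N_rare ≤ 1, or C_ACE ≤ 0) fall back to Chao1.

**Rarefaction** is individual-based: subsamples of size n are drawn
without replacement from the pool of specimens implied by the counts,
at n = step, 2·step, … (default step 50), with the full pool always
the last point. Each of the `reps` replicates (default 100) shuffles
the pool once and evaluates the estimator on growing prefixes, so every
size-n subsample is uniform over size-n subsets while one shuffle
serves the whole curve; this makes 1000-replicate curves on
10⁴-specimen pools cheap. An `exhaustive` mode enumerates all C(N, n)
subsamples for tiny pools, where the mean S_obs curve must (and does)
equal the closed form E[S_obs(n)] = Σ_t [1 − C(N−c_t, n)/C(N, n)].

Curves are summarised by an ordinary least-squares fit of
mean ≈ a·ln n + b; the stopping diagnostic reported at a sample size n
is the fitted derivative a/n (not a finite difference of noisy curve
points, which would inherit Monte-Carlo jitter). A sampling campaign is
conventionally "deep enough" when this slope is small — of order 10⁻³
additional taxa per specimen at n = 3000.

## Composition and taphonomic grades

Composition profiles are column-normalised abundance matrices;
all-zero plots are flagged rather than silently zero-filled. Grade
distributions tally the five ordinal grades (A ≈ fully articulated …
E ≈ isolated fragments) per taxon group or per plot. Ungraded
specimens never enter the A–E denominator but are counted per group.
`fraction_at_grades` sums proportions over a grade set (e.g. the A∪B
"well-preserved" fraction, a proxy for autochthonous burial). Per-taxon
percentages pool specimens over all plots rather than weighting plots
equally; with strongly unequal plot totals these differ, and pooling is
the interpretation consistent with specimen-level reporting.

## Environment clustering

Plots are compared by Bray–Curtis dissimilarity
d(u,v) = Σ|uᵢ−vᵢ| / Σ(uᵢ+vᵢ) on raw aquatic-OTU counts (a `relative`
flag switches to proportions). The aquatic subset is taken either from
a user-supplied OTU list or from the table's habitat annotations, then
filtered to pooled abundance strictly greater than 5 — raw counts are
used because absolute abundance of aquatic taxa is itself the
depth/energy signal being classified.

Agglomeration is average-linkage (UPGMA): the distance between two
clusters is the mean over all cross-pair leaf distances. The
implementation is a direct O(n³) agglomeration (plots number in the
dozens at most) for two reasons: ties on the minimal distance break
deterministically toward the lexicographically smallest pair, making
merge order platform-independent, and height inversions — possible for
average linkage on non-metric dissimilarities — are detected and
reported on the `Dendrogram` rather than hidden. Heights are verified
in the test suite against both a from-first-principles brute-force
recomputation and scipy's independent UPGMA. Cutting the tree into k
groups undoes the k−1 last merges; dendrograms export to Newick with
branch lengths equal to height differences.

Venn summaries report the cardinality of every exclusive region among
up to five plot groups (beyond five the region count explodes and the
display is unreadable); region counts always sum to the union size.

## Co-occurrence networks

Correlations are computed at family level across plots (requiring at
least 3 plots): Pearson's r with the two-sided t test on n−2 degrees of
freedom, Spearman's ρ with the analogous t approximation on ranks, and
Kendall's τ with the exact small-sample null when the data are tie-free
(scipy's exact method; with ties it uses the asymptotic normal
approximation — a full permutation null under ties was judged not worth
the cost at these n). Families with constant counts across plots have
no defined correlation; they are excluded and flagged. No
multiple-testing correction is applied by default, since the edge rule
is deliberately a liberal screen; the p-values are exported so users
can apply their own.

An edge joins two families when r > r_min (default 0 — negative
associations are never linked) and p < p_max (default 0.1), both
strict. At nine plots the Pearson rule is equivalent to |r| > 0.5822
with positive sign, which the tests verify by inverting the t
distribution. Edgeless families stay in the graph as flagged isolates.

**Double zeros.** Two taxa jointly absent from many plots correlate
positively for reasons that need not be ecological (detection limits,
non-overlapping activity periods). The default reproduces the plain
calculation; `drop_double_zero=True` recomputes each pair over only the
plots where at least one member is present, and pairs left with fewer
than three informative plots or a constant sub-vector become
non-edges. The test suite asserts the option strictly shrinks |r| (or
drops the pair) on a matched-zeros fixture.

**Module detection** uses the Louvain algorithm, implemented in the
package: greedy single-node moves to the neighbouring community with
the largest modularity gain, followed by graph aggregation, repeated to
a fixed point. Node-visit order is shuffled by a generator seeded per
run, and ties in the best gain (including "stay put") are broken
uniformly at random — the tie randomization matters, because a
stay-on-tie rule provably freezes some small graphs in suboptimal
partitions that no restart can escape. `detect_modules` runs
`restarts` seeded passes (default 10) and keeps the partition with the
highest modularity; the suite checks the result equals the exhaustive
maximum over all partitions on 200 random graphs of ≤ 8 nodes.
Isolated nodes become singleton modules. (networkx's Louvain was not
usable as a backend: its current release can enter an infinite loop on
equal-gain oscillations; igraph's multilevel implementation terminates
but is effectively insensitive to the seed, defeating restarts.)

**Agreement scoring.** A reference assignment maps families to one or
more habitat categories (e.g. Aquatic / Mudflat / Edaphic / Silvan) and
to an aquatic/terrestrial life habit. Each detected module is mapped to
the category holding the plurality of its members, ties broken toward
the globally larger category and then lexicographically — the mapping
rule is a package convention, declared here because plurality mapping
admits variants. A node is correct when its module's mapped category is
among its own reference categories; the reported fraction is over
nodes present in the reference, with absent nodes listed separately.
The bipartite family-category reference graph is also constructible for
visual comparison.

## Synthetic communities

The generator (`taphonet.synthetic`) draws specimen tables from a
declarative `CommunityConfig`: plots grouped into localities and true
environments; named habitat modules, each active on a subset of plots;
per-OTU mean abundance when active vs. background, grade probability
vectors, and a negative-binomial count law (dispersion configurable)
reflecting the patchiness of fossil concentrations. A single seed fixes
every draw, so a configuration regenerates byte-identical tables, and
each table ships with its ground truth (OTU→module, family→category,
family→habit, plot→environment).

`default_community()` is the package's standard study condition:
nine plots in three localities across three environments (shoal, bay,
shallow lake); a clam-shrimp-like OTU at ~90% of shoal-plot specimens
(mean 1800 of ~2000 per plot); water-boatman- and mayfly-naiad-like
dominants along the depth gradient; mudflat, edaphic, silvan and forest
terrestrial modules of 4–5 families each; an 18-OTU rare terrestrial
tail; grade vectors that put roughly 70–75% of specimens at A∪B; and a
4.5% order-level identification failure rate. These values were chosen
once as a realistic lake-margin configuration and are not tuned per
analysis.

`planted_modules_community()` is the pipeline benchmark: fifteen plots,
five modules of five families each, every module co-active on its own
disjoint triple of plots at mean 30 (background 0.3, dispersion 5).
Disjoint active sets make within-module correlation strongly positive
and between-module correlation negative, so the positive-correlation
filter isolates dense blocks — the regime in which correlation
screening plus Louvain should succeed, and does (mean node-assignment
agreement ≥ 0.9 over 100 seeds in the test suite; typically 1.0).

What the generator does **not** emulate: transport physics or
time-averaging mechanisms (grades are drawn i.i.d. per OTU, not from a
distance model); abundance correlation between stages of the same
species; spatial autocorrelation between adjacent plots beyond shared
module activity; and observation-level identification biases other than
the flat order-loss rate. Passing tests therefore demonstrate that the
algorithms recover planted statistical structure of the kind described,
not that real assemblages satisfy those generative assumptions.

## Numerical conventions and edge cases

* Counts are validated as nonnegative integers; abundance filters use
  strict inequality (pooled count > threshold).
* Bray–Curtis of two all-zero vectors is an error (0/0), not 0.
* `cut_clusters` accepts 1 ≤ k ≤ n and labels groups by first
  appearance in leaf order, so labels are stable across runs.
* Correlation p-values on the diagonal are 0 by convention; NaN
  correlations (degenerate pairs) never produce edges.
* Significance stars in the exported semimatrix: `***` p<0.01, `**`
  p<0.05, `*` p<0.1.
* All stochastic steps (rarefaction, generator, Louvain) take explicit
  seeds; CLI runs echo every parameter and seed into a manifest, and
  rerunning a config reproduces artifacts bit-for-bit.

## Problem sizes used in validation

The shipped validation uses the default community (~11–14k specimens,
9 plots, ~35 OTUs), per-plot rarefaction at step 50 with 50 replicates,
100 seeds of the planted-module benchmark, brute-force oracles on
instances of ≤ 6 plots (clustering) and ≤ 8 nodes (modularity), and
1000-replicate Monte-Carlo rarefaction checks on pools of ≤ 1200
individuals. These sizes make the full suite run in well under a minute
while keeping every oracle exhaustive where exhaustiveness is claimed.

## Known limitations

* Co-occurrence is correlation, not interaction: the network is a
  screen for shared depositional/habitat signal, and the double-zero
  caveat above applies to all of it.
* With nine plots, even the exact Kendall null has limited resolution;
  p < 0.1 is a liberal screen, not a discovery threshold.
* Louvain with restarts has no optimality guarantee in general; the
  exhaustive-maximum property is verified only at small graph sizes.
* The agreement score depends on the declared plurality mapping; other
  module-to-category rules (e.g. optimal matching) can differ by a few
  percentage points on the same partition.
* Reference assignments built from living relatives (taxonomic
  uniformitarianism) are themselves hypotheses; disagreement between
  modules and reference is evidence about either side.
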