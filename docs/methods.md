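# Methods

## Network construction

Edges are defined by marginal Pearson correlation: traits *i* and *j* are
connected iff |r_ij| > 0.2 (strict) and the two-sided p-value is below 0.05
(strict). p-values use the exact t-transform t = r·√((n−2)/(1−r²)) with
n − 2 degrees of freedom rather than a normal approximation, because site
networks are built from only 15 trees. Correlations are pairwise-complete:
rows with a missing value for one trait still contribute to every pair they
complete. Traits that are constant within a site are flagged and kept in
the node set without edges, so all networks over a study share one node set.

Two readings of the construction rule are possible — binary adjacency for
the topology metrics with |r| carried for display, or |r|-weighted metrics
throughout. We compute all topology parameters on the **binary** adjacency
(the retained coefficients are "set to 1" before anything else) and attach
the signed coefficient and |r| weight as edge attributes for export and
visualisation only. Negative correlations form edges exactly like positive
ones; sign is never a filter.

No multiple-testing correction is applied by default — the construction
rule is a per-pair decision, and correcting it would change the method
being studied. `RunConfig(p_adjust="bh")` applies Benjamini–Hochberg to the
pairwise p-values for sensitivity analyses; it can only remove edges.

## Topology parameters

* edge density 2E/(N(N−1));
* diameter = maximum finite geodesic, and average path length = mean
  geodesic over **reachable** ordered pairs. Site networks at n = 15 trees
  are often disconnected; restricting to reachable pairs keeps both metrics
  finite without discarding nodes. The number of components is always
  reported alongside, and `RunConfig(path_scope="largest_component")`
  switches to largest-component-only statistics;
* average clustering coefficient = mean of the local coefficient
  C_i = 2e_i/(k_i(k_i−1)) over **all** nodes, counting degree-0/1 nodes as
  C_i = 0 (the network value averages every trait, not just connected ones);
* modularity = Newman Q of a community partition found by deterministic
  greedy agglomeration (Clauset–Newman–Moore). Determinism makes tests
  exact and reruns identical; on the ≤ 8-edge graphs where exhaustive
  search is feasible, the greedy optimum averages ≥ 95% of the true
  optimum, and it is exact on separable structures (disjoint cliques,
  bridged cliques). An edgeless network has Q = 0 with singleton modules;
* node parameters: degree; closeness with the Wasserman–Faust scaling
  (reach/(N−1)) · (reach/Σd), which is 0 for isolated nodes and lies in
  [0, 1]; betweenness by Brandes' algorithm, fractionally credited over
  multiple geodesics and left unnormalised. Trait-network analyses use
  node metrics only ordinally (hub ranking), so the scale conventions are
  fixed here and stated explicitly.

## Variability

CV = 100·sd/mean with the sample (n − 1) standard deviation by default
(`cv_convention="population"` switches). The category-level aggregate has
no canonical definition; two are reported side by side: the mean of
member-trait CVs (headline) and the CV of the member-trait CVs (the
between-trait spread). Network-parameter variability is the max/min/mean/CV
of each whole-network parameter across sites, excluding the pooled row.

## Environment association

PCA is performed on the factor **correlation** matrix (factors
z-standardised) because climate and soil factors carry incommensurable
units; loadings are unit eigenvectors with a deterministic sign convention
(largest-magnitude entry positive). Representative factors are selected
greedily: for each retained component in order, the not-yet-chosen factor
with the largest absolute loading. Parameter–factor association is plain
Pearson correlation with an OLS line for plotting. Site clustering uses
Ward linkage on Euclidean distance over the z-standardised, concatenated
climate + soil table (the Ward.D2 convention of
`scipy.cluster.hierarchy.linkage(method="ward")`), cut at k = 2.

## Variance partitioning

For each network parameter y over sites, three OLS fits — climate block,
soil block, both — give R²_C, R²_S, R²_F, and inclusion–exclusion yields
the unique climate fraction a = R²_F − R²_S, unique soil fraction
b = R²_F − R²_C, shared fraction c = R²_C + R²_S − R²_F and residual
d = 1 − R²_F. The headline fractions use **adjusted** R² (the standard
variance-partitioning convention; with 6 predictors at 20 sites raw R² is
badly inflated), with the raw-R² versions reported alongside. Adjusted
fractions can be negative; they are reported as-is, never clipped, because
clipping would silently break the closure identity a + b + c = combined.
Predictors default to the three PCA representatives per block. Cross-block
collinearity is legitimate (it is what the shared fraction measures) and is
handled by pinv-based fits; within-block collinearity raises an error.

Block significance uses a permutation test: site labels of the response are
permuted (999 by default), and p = (1 + #{R²_perm ≥ R²_obs})/(1 + n_perm),
never exactly 0. Permuted R² values are computed by pushing all permuted
responses through the hat matrix of the fixed design at once — the same
algebra as refitting, verified against explicit refits in the tests, and
calibrated: under a null response the rejection rate at α = 0.05 falls in
[0.03, 0.07] over 1000 simulations.

## The synthetic-study generator

`synth.generate_study` emulates the survey design the pipeline targets:
20 sites × 15 trees × 27 traits in three functional modules. Per site,
traits are multivariate normal with within-module correlation ρ_w and
across-module correlation 0.05; an aridity-like gradient g_s ∈ [0, 1]
(default: evenly spaced along the site sequence) modulates coordination
strength linearly, ρ_w(g) = 0.65 + 0.2·(g − ½). The environment acts on
correlation *structure*, not trait means, because network topology — not
trait levels — is the object of study. The defaults were chosen so the
generated regime matches what field LTNs look like: the weakest site's
ρ_w = 0.55 stays above the n = 15 significance cut (|r| ≈ 0.514), so site
networks never collapse, clustering coefficients stay moderate and stable
(CV ≈ 17% across sites) while diameter varies most — the spread ordering
observed in real multi-site networks. Trait means default to distinct
positive scales with sd = 0.2·mean (CV ≈ 20%, typical of leaf traits).
Configs whose implied correlation matrix is not positive semi-definite at
any site are rejected before sampling.

Climate (19 factors, BIO1–BIO19) and soil (11 factors) tables are linear
functions of site-level latent signals plus independent noise
(sd 0.3), organised in three planted factor blocks per table (sizes 7/6/6
and 4/4/3). Latents are made exactly mutually orthogonal, and the blocks
carry distinct strengths (1.3/1.0/0.75) so the factor-correlation
eigenvalues are well separated — equal-strength blocks would give
near-degenerate components and unidentifiable representatives. Climate
block 1 *is* the gradient; soil block 1 echoes it with mixing weight 0.35.
Climate is therefore the causally dominant driver by construction, and the
pipeline's job is to recover that.

What the generator does **not** emulate: non-Gaussian trait distributions,
spatial autocorrelation between neighbouring sites, missing data patterns,
measurement error structure, or trait-mean responses to the environment.
Passing tests therefore demonstrate correctness of the computations and
recoverability of planted structure under idealised sampling — not that any
field dataset will show these effects at these magnitudes.

## Numerical choices and degenerate inputs

* Threshold ties (|r| = 0.2 or p = 0.05 exactly) are excluded — the
  inequalities are strict.
* Edgeless networks: path statistics (0, 0) with a warning, Q = 0,
  singleton modules.
* Zero-variance traits/factors: flagged and excluded from edges (traits)
  or dropped (PCA factors), never silently imputed.
* Permutation p-values use the +1 convention and a single seeded
  `numpy.random.Generator` per run; all generator seeds are explicit.
* The acceptance script reports problem sizes alongside each value; it
  uses the default study size (20 × 15 × 27) and 999 permutations.

## Known limitations

* Greedy modularity is a heuristic; on networks with weak or ambiguous
  structure its partition (hence Q) can differ from the global optimum.
* Representative selection is purely |loading|-greedy; an analyst choosing
  representatives with domain judgment may pick differently from the same
  PCA, so downstream association and VPA results depend on that convention.
* Adjusted-R² fractions at 20 sites are noisy; negative fractions are
  expected for weakly coupled responses and should be read as ≈ 0.
* With 15 trees per site the per-site correlation significance cut is high
  (|r| ≈ 0.514), so site networks under-represent moderate correlations by
  design of the construction rule.
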