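# Methods

This note documents the models, conventions and design choices behind the
package, in the order data flows through the pipeline.

## Synthetic cohorts

**Planted network.** Nodes are split into `n_modules` contiguous blocks of
near-equal size; each within-module pair receives an edge with probability
`p_within`, each between-module pair with `p_between` (defaults 0.4 /
0.02, which give a 148-node graph of edge density ≈ 0.08, below the lowest
analysis density so the full planted structure is always inside the
thresholded graphs). The per-pair uniform draws are a deterministic
function of the seed and are shared across design cells, so variants that
modulate `p_between` (the genotype effect) are coherent perturbations of
one network rather than independent graphs.

**Hubs.** Designated hub nodes are raised by preferential rewiring: edges
between non-hub nodes are moved onto the hub until its degree reaches
mean + 4 SD of the degree sequence (bounded retries, then an error naming
the infeasible node). The +4 SD target is deliberately far above the
+2 SD hub-detection convention: with a realistic handful of hubs per
network (the default cohorts plant six per group, four shared and two
group-unique, mirroring the partially overlapping hub distributions
reported for patient vs control connectomes) the hubs themselves inflate
the SD of the nodal centrality distribution, and hubs planted at the
detection boundary would mask each other. Afterwards, non-designated
nodes whose degree exceeds mean + 1.5 SD by chance are rewired down
(edges moved to low-degree nodes): a binomial background leaves ~2% of
nodes above +2 SD, and if such chance hubs survive, the designated list
is not the complete ground truth that recovery tests assume. Both steps
preserve total edge count.

**From graph to covariance.** The precision matrix is Ω = I − c·A with
coupling c > 0; the covariance is Ω⁻¹ = I + cA + c²A² + …, so connected
pairs carry positive correlation ≈ c plus path terms, and unconnected
pairs only the (strictly smaller) path terms. Ω is positive definite iff
c < 1/λ_max(A) (A is nonnegative, so its spectral radius equals its
largest eigenvalue); the default coupling is 0.85/λ_max(A), and any
explicit coupling is validated by Cholesky with an error instructing a
smaller value. The sign convention matters: a *positive* off-diagonal
precision would plant negative edge correlations, which density
thresholding by signed value would never select.

**Group and genotype effects.** The group effect multiplies within-module
edge weights in group B by (1 − `group_effect`); the default 0.5 halves
within-module coupling, producing the planted clustering deficit. The
genotype effect multiplies `p_between` by (1 ± `genotype_effect`) for
S-carriers, with opposite sign in the two groups — raising between-module
connectivity lowers modularity and small-worldness — reproducing a
crossed genotype-by-group pattern. Both magnitudes are free parameters of
the design.

**Time series.** Each subject's series is a stationary Gaussian AR(1):
x_t = φ·x_{t−1} + √(1−φ²)·ε_t with ε_t ~ N(0, Σ) and x_0 ~ N(0, Σ), so
the lag-0 covariance equals Σ at every t for any φ ∈ [0,1) — the temporal
model widens the sampling noise of correlation estimates without biasing
them. Default φ = 0.3, a modest autocorrelation typical of 2-second
sampling. A constant baseline of 500 is added so series have a
BOLD-like positive mean and a meaningful temporal SNR (≈ 500, comfortably
above the quality gate). Defaults of 250 timepoints and 30+30 subjects
match a conventional single-site resting-state study.

**Morphometry.** Node volumes differ between groups by
`volume_coupling` × (planted degree difference) + N(0, `noise_sd`) per
node, with subject-level scatter of the same SD around the group mean;
thickness follows the same law at 1/100 scale. With `noise_sd = 0` the
structure–function regression is exact (R² = 1, slope = coupling).

**What the generator does not emulate.** No hemodynamic response, scanner
drift, head motion, spatial autocorrelation between neighboring parcels,
or non-Gaussian BOLD noise. Passing tests therefore demonstrate that the
pipeline recovers structure *of the kind planted* — linear correlation
structure with known topology — not robustness to fMRI artifacts, which
enter real analyses upstream of this package's inputs.

## Conditioning

Temporal SNR is the column mean over the column SD (n−1 denominator),
averaged over ROIs; subjects at or below the threshold (default 100) are
excluded and logged. Slice-level tSNR is not computable from parcellated
series, so the per-ROI mean stands in for it. Constant columns report
+∞ with a warning rather than raising — a flat channel is a data-quality
observation.

Band-pass filtering is a zero-phase forward-backward Butterworth of order
4 (effective order 8 after filtfilt); zero phase cannot shift one
region's signal against another, which would bias correlations. Default
cutoffs are 0.005–0.1 Hz. The conventional printed low-pass value of
40.1 Hz is physically impossible at a 2.009 s sampling interval (Nyquist
≈ 0.249 Hz) and is treated as a configuration left to the user; 0.1 Hz is
the standard resting-state choice.

Nuisance regression projects each ROI onto the orthogonal complement of
an intercept plus the supplied regressors (typically global signal, white
matter, CSF and six motion parameters); residuals are exactly zero-mean
and orthogonal to every regressor, and rank-deficient designs raise an
error listing the collinear columns. The default stage order is
regression then filtering; the reverse is available since the two do not
commute exactly, and on series without nuisance structure the whole stage
leaves expected correlations unchanged to within 0.02.

## Connectome construction

Association matrices are pairwise Pearson correlations (constant columns
and fewer than 3 timepoints are errors). Binarization keeps the top
⌈d·n(n−1)/2⌉ off-diagonal pairs ranked by signed correlation — at
densities ≤ 0.5 strong negative correlations are never selected, matching
common practice — with deterministic tie-breaking by (value, then
lexicographic node pair) so results are platform-independent and the
graphs are exactly nested across the sweep. Ranking by |r| and absolute-r
thresholding are available as configuration (`negatives`,
`threshold_mode`) because the alternative readings of a "0.1–0.5
threshold range" are defensible. Group-mean matrices average entries in
Fisher-z space, which avoids the downward bias of naive averaging near
|r| = 1.

## Graph metrics

Implementations are vectorized (clustering from the diagonal of A³,
shortest paths by sparse BFS) or delegate to networkx (betweenness,
Louvain); all of C, L, E, bᵢ and r are verified exactly against naive
brute-force re-implementations on every connected graph with ≤ 6 nodes.

Conventions for disconnected graphs, which the low-density end of the
sweep produces routinely: L averages over connected pairs only and
reports the count of disconnected pairs; E handles disconnection natively
(1/∞ = 0); σ is computed on the largest connected component. An edgeless
graph has E = 0 and undefined (NaN) L. Assortativity is undefined (NaN
with a warning) on regular graphs, where endpoint degrees have zero
variance.

Modularity takes the best of 10 seeded Louvain restarts (the heuristic is
stochastic; restarts trade time for stability) and always at least
matches the trivial single-community partition (Q = 0). σ uses 20
degree-preserving nulls of 10 accepted double-edge swaps per edge by
default; both are configurable and recorded in the profile. When the
swap-attempt budget runs out on small dense graphs, the partially rewired
graph is accepted with a warning — every accepted swap preserves the
degree sequence, so it is still a valid null, just less mixed; a graph
admitting no swap at all raises. AUC summaries use the trapezoid rule;
NaN entries restrict the integral to the longest contiguous finite run
with a warning.

## Hubs

Hub scores are nodal centrality (degree or betweenness) AUCs across the
sweep, computed on the group-mean association matrix; nodes above
mean + k·SD (default k = 2) are hubs. A single-density sweep scores by
the centrality itself. k = ∞ is an explicit empty-set sentinel. The
group-mean-matrix route (rather than per-subject hub votes) was chosen
because it is the construction that yields a single group hub network to
tabulate and compare; the threshold and aggregation are configurable.
One caveat follows from order statistics: across ~148 roughly Gaussian
nodal scores the top background score sits near +2.5 SD, so with very few
genuinely exceptional nodes the rule will flag a chance node or two —
false-positive control improves as the true hub set grows and inflates
the SD.

## Inference

Permutation tests permute group labels (difference of means by default,
median optional) and use the add-one estimator
p = (1 + #{|t*| ≥ |t|})/(n_perm + 1), which cannot report zero and is
uniform under the null to the resolution of n_perm. Mann–Whitney U counts
pairs with tie splitting; p-values are exact for tie-free groups of ≤ 8,
otherwise normal approximation with continuity and tie correction (all
values identical gives p = 1 rather than an undefined statistic).
Global metrics are deliberately not corrected across the six-member
family; nodal contrasts are Benjamini–Hochberg corrected across regions.
Metric–covariate associations use Spearman's ρ (rank-based, robust to the
non-normality of graph metrics); Pearson is a configuration switch.
Structure–function fits are OLS of per-node centrality differences on
per-node structural differences restricted to a named region set, with
group differences taken as mean(A) − mean(B) on both axes.

The genotype-within-group contrast is literally the group contrast code
with a different grouping column, and a test verifies the two produce
identical U statistics and effect sizes on the same subgroup.

## Reproducibility and problem sizes

Every stochastic step (generation, Louvain restarts, null rewiring,
permutations) derives its seed deterministically from the study seed via
`numpy.random.SeedSequence` spawn keys, and reports are written with
sorted keys — identical seeds and inputs give byte-identical output
files.

Calibration and recovery checks use the study conditions stated above
(148 nodes, 30+30 subjects, 250 timepoints, the nine-density sweep) for
planted-effect recovery, and smaller graphs (20–100 nodes) with reduced
null/restart counts for the distributional calibrations, sizes chosen so
the full validation battery completes in minutes on one CPU while keeping
every Monte Carlo band at least three standard errors wide.

## Known limitations

- Louvain is a heuristic; Q is a lower bound on the optimum and the
  partition is only seed-stable, not canonical.
- σ on very sparse graphs depends on the largest-component convention;
  values at d = 0.10 for 148 nodes occasionally rest on ~90% of nodes.
- The Gaussian generative model cannot produce negative planted edge
  correlations or heavy-tailed connectivity, and genotype effects act
  only through between-module density.
- Absolute-r thresholding (`threshold_mode: absolute`) yields graphs of
  varying density across subjects; the density-sweep invariants
  (nestedness, realized density) apply to the default density mode.
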