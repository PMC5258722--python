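# Methods

## The model and its assumptions

The test compares clustering *structure*, not cluster means.  Its data
model: every subject i of population j yields a symmetric nonnegative
N x N dissimilarity matrix A_ij over the same N items with a zero
diagonal; within a population, subjects are exchangeable draws around a
population-level matrix.  The null hypothesis is that all k populations
share one clustering structure; the alternative is that at least one
population clusters the items differently.

Two reductions make the statistic tractable.  First, all inference runs
on *averaged* matrices — the per-population means Ā_j and the pooled
weighted mean A̿ — so subject-level heterogeneity enters only through the
sampling variability of those means.  Second, clustering quality is
summarized by the silhouette vector, so "same structure" is
operationalized as "same per-item silhouette profile under the pooled
labeling".  The global statistic ΔS = Σ_j ‖S − S_j‖² and the per-item
statistic Δs_q = (S_q − mean_j S_{j,q})² are both zero exactly when every
population's average matrix yields the pooled silhouettes.

### Silhouette conventions

The within-cluster dissimilarity a_q is the average of item q's distances
to *all* |C| members of its cluster, including its own zero self-distance
(divide by |C|).  The classical Rousseeuw convention divides by |C| − 1;
it is available as `classical_a=True` and changes a_q by the factor
|C|/(|C| − 1).  Singleton clusters score exactly 0, and a single-cluster
labeling scores 0 everywhere (no "second-best" cluster exists) with a
warning.  Matrices are symmetrized as (D + Dᵀ)/2 on ingest; asymmetry
beyond 1e−8 relative to the largest entry triggers a warning rather than
an error, since small asymmetries are usually file-precision artifacts.

### The bootstrap null

Group labels are exchangeable under the null, so each replicate draws
n_j subjects per group with replacement *from the pooled set of all n
subjects*, rebuilds Ā*_j and A̿*, re-derives labels, and recomputes both
statistics.  P-values are the fraction of replicates at least as large
as the observed value; ties count toward the numerator.  Design choices
here:

- **Reclustering.** By default each replicate re-clusters its own A̿*
  (`recluster_bootstrap=True`), so the null distribution includes the
  variability of the labeling step.  Setting it to `False` reuses the
  observed labels — roughly 3x faster and conditions the test on the
  observed clustering.
- **Number of clusters.** k is estimated (or given) once on the observed
  A̿ and held fixed across replicates; re-estimating k per replicate is
  not part of the procedure and would multiply runtime by the size of
  the candidate grid.  The choice is recorded in the result metadata.
- **P-value estimator.** The plain fraction can return 0; the
  `add_one` option uses (1 + count)/(B + 1), which cannot, and is the
  sensible choice whenever the p-values feed a Bonferroni correction.
- **Degenerate replicates.** If a replicate produces an empty cluster or
  a degenerate affinity, it is redrawn (at most 10 times) before the run
  errors out.
- **Resolution.** With B replicates no p-value can drop below 1/(B+1)
  (add-one) or 0 (plain).  In strong-signal regimes many items tie at
  that floor; the observed Δs_q then carries the ranking information,
  and result tables should be sorted by (p, −Δs_q).  This is a
  resolution limit of any bootstrap test, not an artifact of this
  implementation.

### Multiple testing and the robustness filter

Per-item p-values are Bonferroni-adjusted: min(1, m·p) with m the number
of items actually tested.  When the same study has been processed two
ways (the motivating case: fMRI with and without motion scrubbing), the
robustness filter keeps only items whose unadjusted p-values agree within
0.05 between the two runs, and the Bonferroni adjustment is then redone
over the kept items only (`anocva compare-runs`).

## Clustering route

Dissimilarity → affinity → symmetric normalized Laplacian
L = I − D_w^{−1/2} W D_w^{−1/2} → eigenvectors of the k smallest
eigenvalues → rows normalized to unit length → k-medoids (PAM) on the
embedded rows.  Affinity options: the parameter-free linear map
W = 1 − D/max(D) (default; monotone, no bandwidth to pick) and a
Gaussian kernel exp(−D²/2σ²) with σ the median off-diagonal distance.
Isolated items (zero affinity row) receive a tiny degree (1e−12) with a
warning rather than crashing the normalization.

PAM runs a greedy deterministic BUILD start plus 4 seeded random starts,
each followed by best-improvement SWAP iterations until convergence; the
lowest within-medoid total wins and ties break toward the lowest object
index.  k-medoids rather than k-means because medoids are actual objects
and the objective is robust to outlying embedded rows.  On instances of
up to 9 objects the multi-start PAM reproduces the exhaustive optimum in
all tested cases; a single greedy start occasionally lands in a local
optimum, which motivated the restarts.

### Choosing the number of clusters

For k = 2..k_max the pooled matrix is clustered and the average
silhouette s̄(k) recorded.  The silhouette criterion picks the arg-max of
s̄(k).  The slope criterion picks the arg-max of
−(s̄(k+1) − s̄(k)) · s̄(k)^p (default p = 1, exposed as `slope_p`),
rewarding a high level followed by a sharp drop.  Ties break toward the
smallest k.  A caveat learned from the simulations: when within-cluster
spreads are *graded* (every cluster looser than the last), the
silhouette-curve drops grow with k — each successive split hits a
tighter, higher-silhouette cluster — and the slope criterion then
systematically overshoots by one.  It behaves as advertised when the
spread inequality is concentrated (e.g. one large loose cluster among
tight ones), which is the regime its robustness claim is about.

## The synthetic generator

`SyntheticSpec` plants a block structure: items share a cluster label per
group; the base matrix has mean within-cluster dissimilarity `mu_within`
(scalar, or one value per cluster to model unequal spreads) and
between-cluster dissimilarity `mu_between`; each subject adds i.i.d.
symmetric Gaussian noise (`noise_sd`), clipped at zero with a zeroed
diagonal.  Group 2's labels differ from group 1's exactly on
`effect_items` (each moved to the cyclically next cluster), so an empty
set gives an *exact* null: all subjects i.i.d. regardless of group, which
is precisely the exchangeability the bootstrap assumes.  Clipping biases
the noise slightly near zero but preserves that exchangeability, which is
all the calibration results rely on.

Default scenario constants — N = 20 items, 3 planted clusters,
mu_within = 0.3, mu_between = 0.7, noise_sd = 0.05, 15+15 subjects — are
arbitrary test-scale conventions chosen so that a single subject's matrix
is individually informative but the group averages are not trivially
noise-free; they are not estimates of any real dataset.

The time-series companion gives each planted cluster a standard-normal
latent signal; item q observes latent_weight·z_cluster(q) +
idiosyncratic_sd·ε, so expected within-cluster correlation is
w²/(w² + σ²) and between-cluster correlation is zero.  It exercises the
correlation-to-dissimilarity route (default metric 1 − |r|, treating
anticorrelation as similarity; 1 − r and √(1 − r) available).

What the generator does *not* emulate: site effects, motion artifacts,
spatial autocorrelation of real parcellations, heavy-tailed subject
heterogeneity.  Passing calibration on these synthetics shows the
bootstrap logic and implementation are sound under exchangeability; it
does not certify behavior under real-data violations of it.

## Simulation scales and observed behavior

The calibration run uses 200 Monte-Carlo null studies (15+15 subjects,
N = 20, 3 clusters) at 200 bootstraps each — small enough to run in about
a minute, large enough that the exact binomial 95% band around a 5%
rejection rate (4–16 rejections in 200) is discriminating.  Measured
rates in repeated runs land around 0.035–0.045, i.e. calibrated with a
mild conservative tilt, consistent with reclustering variability
inflating the null tail slightly.

The power scenario plants 5 clusters and moves one item per cluster in
group 2 (items 1, 5, 9, 13, 17 of 20) at noise_sd = 0.05.  Moving one
item out of and into each cluster keeps cluster sizes constant, so
cluster-mates' silhouette shifts largely cancel between the pooled matrix
and the per-group average, concentrating the per-item statistic on the
moved items (observed Δs_q about two orders of magnitude above
neighbors').  The global test rejects at the bootstrap floor and the five
moved items rank first by (adjusted p, −Δs_q).  With equal group sizes
and larger perturbed fractions the per-item statistic partially cancels
for the moved items themselves (their pooled silhouette sits midway
between the groups' ±s), a structural property of the statistic worth
knowing when interpreting item-level results.

## Numerical notes

- Averaging identical matrices over groups of different sizes can differ
  in the last ulp, so "ΔS = 0" claims are asserted at 1e−24 rather than
  exactly; p-values are unaffected because replicate statistics inherit
  the same wobble.
- Eigenvector sign and degenerate-eigenvalue rotations do not affect the
  k-medoids step (distances between embedded rows are invariant to
  orthogonal column transformations within an eigenspace) but can in
  principle differ across LAPACK builds; determinism is guaranteed within
  one environment, not across BLAS implementations.
- All randomness flows through `numpy.random.default_rng(seed)`; the
  bootstrap consumes the stream only for subject index draws, in a fixed
  order, so results are bit-reproducible for a given seed.

## Limitations

- The pooled-resampling null tests group exchangeability; a within-group
  permutation test is deliberately not offered.
- Only the spectral/k-medoids clustering route ships, though the
  statistics accept any fixed labeling, so a user-supplied clustering can
  be composed manually via `average_dissimilarity` + `anocva_statistics`.
- Bonferroni is the only multiplicity correction, matching the intended
  reporting convention; FDR control is out of scope.
- No neuroimaging file formats: inputs are plain matrices or item x time
  tables; upstream preprocessing (parcellation, scrubbing, nuisance
  regression) is assumed done elsewhere.
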