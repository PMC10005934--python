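# Methods

## Model

The analysis treats each subject's binarized structural connectome as the
coupling matrix of a noise-free discrete linear time-invariant system
`x(k+1) = A x(k) + B u(k)`. This is the standard simplification in
structural brain controllability work: regional dynamics are clearly
nonlinear, but linear controllability lower-bounds local controllability of
the linearized system, and the two node metrics derived from it (average
and modal controllability) are interpretable functions of the graph's
spectrum.

**Edge definition.** An edge is present when at least `min_streamlines = 3`
tractography streamlines connect two regions; edges carry no weight
afterwards. The rule is applied per subject (not to a group-consensus
mask): the inclusion criterion is stated per connection, and per-subject
application keeps each subject's system matrix a function of that subject's
data alone. Symmetry, zero diagonal, non-negative integer counts, FA in
[0, 1], and FA/count support consistency are *checked* at load time, never
silently repaired — an asymmetric input matrix indicates an upstream
pipeline fault, not a formatting issue.

**Stabilization.** The Gramian series `Σ A^i B Bᵀ (Aᵀ)^i` converges only
for Schur-stable `A`, and a binary adjacency matrix is never Schur-stable.
Following the convention of the linear-brain-dynamics literature the
adjacency is scaled by `1/(1 + σ_max(A))`, which bounds the spectral radius
by `σ_max/(1+σ_max) < 1` for every input including the empty graph. The
factor is recorded per subject (per-subject normalization is the default
because the statistical analysis is per subject; any common Schur-stabilizing
convention changes absolute values but is recorded and fixed cohort-wide).
Degenerate (edgeless) graphs are processed, not rejected: both metrics are
exactly 1 at every node, and downstream statistics treat such subjects like
any other.

**Controllability.** For symmetric Schur-stable `A_norm` with eigenpairs
`(ξ_n, v_n)` (orthonormal eigenvectors from the symmetric eigensolver):

- average controllability `AC_j = Tr(W_j) = Σ_n v_nj²/(1 − ξ_n²) ≥ 1`,
  with equality exactly for isolated nodes;
- modal controllability `MC_j = Σ_n (1 − ξ_n²) v_nj² ∈ (0, 1]`, equal to 1
  exactly for isolated nodes.

The production path computes both through one eigendecomposition per
subject (O(N³), ~2 ms at N = 114). Eigenvector sign ambiguity is irrelevant
since only `v_nj²` enters. Three independent routes are kept for
validation: the discrete Lyapunov solve `W = A W Aᵀ + e_j e_jᵀ`
(`scipy.linalg.solve_discrete_lyapunov`), the K-truncated series with K
chosen so `ρ^(2K) < 1e-12`, and an impulse-response rollout of the
recursion itself; the test suite requires agreement within 1e-8 at the full
114-node scale. The discrete modal formula `(1 − ξ²)` is used as given by
the discrete-time model (not the continuous-time `(1 − ξ)²` variant).
Whole-brain values are arithmetic means of the node vectors, computed
before any statistical outlier handling; outlier removal then acts on the
aggregated dependent variable within each analysis.

## Quality control

Four per-subject metrics: (1) mean streamline count over present edges,
(2) mean FA over present edges, (3) mean cohort prevalence of the subject's
present edges, (4) mean cohort prevalence of the subject's absent node
pairs. Prevalence (the fraction of cohort subjects carrying an edge after
binarization) is a presence/absence concept, so metrics 3–4 use the
thresholded graphs while 1–2 read raw counts/FA. Metric 4 is implemented as
the mean prevalence over *absent* pairs so that a high value indicates a
subject missing commonly found connections; the metric's verbal definition
admits a region-level reading, and the edge-level reading implemented here
is the one consistent with that directional gloss — it is documented as
such, not asserted as the only computation. Quartiles use linear
interpolation of order statistics (the common "type 7" convention; no
specific quartile rule is canonical for this screen), pooled across the
whole sample rather than per group, and a subject is excluded when any
metric falls strictly below `Q1 − 1.5·IQR` or strictly above
`Q3 + 1.5·IQR`. A subject with an undefined metric (no edges) is flagged.

## Statistics

Each construct is tested by ANCOVA: OLS of the dependent variable on the
effect of interest plus covariates (age, gender, 3-level scanner site,
number of present edges; plus ancestry MDS 1–3 for polygenic-score
analyses; plus medication load in patient-only analyses). Categorical
predictors are treatment-coded against the first declared codebook level —
F and η² are invariant to the coding, so the convention only pins down
coefficient reproducibility. The effect is tested by full-vs-reduced model
comparison (equivalent to Type-III SS for these interaction-free designs),
`partial η² = SS_effect/(SS_effect + SS_resid) = F·df1/(F·df1 + df2)`.

Order of operations per analysis: subset rows → listwise deletion of
missing values among referenced columns (counted) → single-pass removal of
dependent-variable values beyond 3 *sample* SDs of the mean (counted; a
zero-variance column retains everything) → encode → fit. Outlier removal is
applied to the dependent variable only, once, per analysis; per-analysis
exclusion counts are logged rather than claimed to match any external
bookkeeping.

The 95% CI on partial η² is a percentile interval over 1000 case resamples
(rows drawn with replacement from the post-exclusion sample; BCa was not
used because plain resampling with replacement is the procedure being
mirrored). Resamples with rank-deficient designs — possible when a rare
factor level drops out — are redrawn and counted, and the analysis errors
out if more than 10% of resamples degenerate. The bootstrap uses a
vectorized normal-equations path for speed; a test pins it to the
statsmodels OLS fit to 1e-10.

Regional analyses fit the same ANCOVA per node (per-node outlier removal)
and correct across the parcellation with Benjamini–Hochberg at q = 0.05;
constructs are tested independently with no cross-construct correction. A
node whose fit fails is recorded with its error and excluded from the BH
procedure rather than aborting the screen.

Randomness: a single pipeline seed is expanded through
`numpy.random.SeedSequence` into independent substreams per stage and per
subject, making every artifact bit-reproducible from (inputs, config, seed).

## Synthetic cohorts

The generator emulates the features of tractography cohorts that this
pipeline is sensitive to, with defaults at the study scale (114 nodes, 820
controls, 692 patients):

- **Backbone**: lognormal expected-degree weights (`hub_strength = 0.6`,
  coefficient of variation of expected degree ≈ 0.55) give a Chung–Lu-style
  prevalence matrix scaled to mean subject-level density 0.20 and clipped
  to [0, 0.995] — a high-prevalence hub core with a rare periphery.
- **Subjects**: edges are Bernoulli draws at the (possibly effect-shifted)
  prevalence with a 2% symmetric flip rate; present edges get integer
  streamline counts falling below the 3-streamline threshold with
  probability 0.15 (uniform on {1, 2}) and otherwise
  `3 + NegBinomial(r = 1.2, mean 15)` (overdispersed, mean ≈ 18), so
  binarization is non-trivially exercised; FA is Beta(4.5, 5.5)
  (mean ≈ 0.45).
- **Covariates**: age uniform 18–65, 65% female, three scanner sites
  (0.30/0.20/0.50), BDI ≈ N(17.7, 11.1) in patients vs N(4.0, 4.2) in
  controls (clipped to the 0–63 instrument range), remission status
  (acute/partial/full at 0.5/0.25/0.25, patients only), familial-risk
  flags, standard-normal polygenic scores with 8% missingness (patients
  only), small ancestry MDS components, Gamma medication load (patients),
  BMI, gender-conditional height, randomized inclusion order.
- **Effects**: the group effect scales hub-edge prevalence for patients by
  `(1 − δ)`; continuous effects scale hub edges per subject in proportion
  to the standardized predictor; regional effects scale all edges of chosen
  nodes; QC-corrupt subjects have a configurable fraction of their edges
  randomly relocated. All injections act at the connectivity level so that
  recovering them exercises the entire binarize → normalize → Gramian →
  ANCOVA chain; a separate outcome-level simulator with exactly known
  coefficients exists solely for calibrating the statistics engine.

Planted-effect magnitudes were calibrated once against the detection
targets: δ = 0.05 for the group effect (ANCOVA power > 0.9 at
n = 200 + 200 — empirically ≈ 1.0) and 0.5 for regional effects (survive
FDR across 114 regions). What the generator does **not** emulate: spatial
embedding and distance-dependent connectivity, scanner-site differences in
the connectomes themselves (site affects only the covariate table),
count–FA correlation, and any real atlas geometry. Passing tests therefore
demonstrate the pipeline's correctness and calibration under a realistic
degree-heterogeneous topology, not agreement with any empirical cohort's
distributions.

## Validation problem sizes

The Monte-Carlo suites run at: type-I error 1000 replicates (n = 200 per
replicate), BH false-discovery proportion 1000 replicates of 114
independent nulls, bootstrap coverage 500 replicates × 1000 resamples
(true partial η² = 0.10 by construction), planted-effect power 20 full
pipeline replicates at n = 200 + 200 × 114 nodes, and 20 null cohorts for
the regional false-positive screen; assertions allow 2–3 binomial standard
errors around nominal values. These sizes keep the full validation suite
within a few minutes while leaving Monte-Carlo error well below the margins
being tested.

## Known limitations

- Weighted-graph controllability, control energy, and target-state
  optimization are out of scope; only binary adjacency dynamics are
  implemented.
- The ANCOVA assumes homoscedastic Gaussian residuals; no site
  harmonization (e.g. ComBat) or mixed-effects modeling is provided —
  site enters as a fixed covariate only.
- The bootstrap CI is percentile, which for very small effects can exclude
  the point estimate's neighborhood asymmetrically; coverage is validated
  at η² ≈ 0.10.
- QC metric 4's published verbal definition is ambiguous (see above); the
  implemented reading is documented and fixed, and its fences are computed
  on the pooled sample, not per group.
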