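# Methods

## The deconvolution model

A methylation profile `y` measured on a heterogeneous sample (whole blood,
a tissue biopsy) is modelled as a linear combination of cell-type-specific
centroid profiles `b_c`:

    y = Σ_c w_c · b_c + ε,    w_c ≥ 0,   Σ_c w_c ≤ 1

with `y` and `b_c` restricted to a small set of marker CpGs that
discriminate the `C` cell types. The weights `w_c` are the cell-type
fractions of interest. The model is linear in *beta* values (methylation
fractions combine linearly when cell populations are pooled), has no
intercept, and tolerates `Σ w_c < 1` so that an unmodelled minor cell type
does not force the fitted fractions to absorb its signal.

Four estimators are implemented. Three fit the regression without
constraints and impose the simplex *a posteriori* (negative coefficients
are zeroed, positives rescaled to sum to one):

* **LR** — ordinary least squares.
* **RPC** — robust partial correlations: a Huber M-estimator fitted by
  iteratively reweighted least squares. The residual scale is MAD/0.6745,
  re-estimated each iteration; residuals within `c = 1.345` scales receive
  weight 1, larger ones weight `c·scale/|r|`. `c = 1.345` is the
  conventional 95%-Gaussian-efficiency constant; iteration starts at the
  OLS solution and stops when the largest coefficient change is below
  1e−6 (cap 50 iterations). With all residuals inside the threshold the
  IRLS fixed point is the OLS fit, so RPC reduces to LR on clean data.
* **SVR** — linear-kernel nu-support-vector regression (the CIBERSORT
  recipe): one fit per nu in {0.25, 0.5, 0.75}, the candidate with the
  smallest RMSE between fitted and observed `y` wins. Features and the
  response stay on the raw beta scale (no z-scoring) so coefficients
  remain interpretable as mixing weights; this is a deliberate deviation
  from CIBERSORT's standardisation.
* **CP** — constrained projection: the least-squares problem with
  `w ≥ 0`, `Σ w ≤ 1` imposed during optimisation. The quadratic program is
  solved with SLSQP using the analytic gradient (the feasible set contains
  the origin so the program is never infeasible); solutions are verified
  in the test suite against a brute-force grid search over the truncated
  simplex at step 0.01. The normalisation is implemented as an
  *inequality*, not an equality.

Estimation is per sample and independent of sample order; reference column
permutations permute the output identically (tested).

## Reference construction

Given purified-cell data with replicates, markers are selected per cell
type by a one-vs-rest moderated-t test: the pooled two-group variance
`s²` (d degrees of freedom) is shrunk towards a prior,
`s̃² = (d0·s0² + d·s²)/(d0 + d)`, with `(d0, s0²)` estimated across CpGs by
moment matching on `log s²` (excess variance over the sampling trigamma
term identifies `d0` via a Newton trigamma inverse; the mean identifies
`s0²`). The moderated statistic is referred to a t distribution on
`d0 + d` degrees of freedom. `d0 = 0` recovers the ordinary pooled t-test,
`d0 = ∞` uses the common prior variance everywhere — both limits are
tested. Exact numerical parity with any particular published
empirical-Bayes implementation is not promised; the limit behaviours and
ranking properties are.

Significant CpGs (Benjamini–Hochberg `q < 0.05`) are optionally restricted
to CpGs overlapping a DNase-hypersensitive site (DHS) of *any* profiled
cell type (DHS intervals are 0-based half-open; CpG positions 1-based;
strand is ignored — DHS are strand-symmetric). The top 50 per cell type by
absolute mean beta difference (ties broken by CpG id for deterministic
builds) form the marker union; centroids are arithmetic means of the
replicates per cell type. Running with the DHS filter absent yields the
"no-DHS" reference through the same code path.

When only one representative profile per cell type exists, the pairwise
recipe replaces the test: CpGs whose beta values differ by more than 0.9
between some pair of cell types are selected (per-pair sets are reported
along with their union). The two recipes are separate modes, never mixed.

## Beta/M transforms and the noise model

`M = log2(b/(1−b))` after clipping `b` into `[ε, 1−ε]`, ε = 1e−6 (a value
is needed so boundary betas map to finite M; the choice only affects the
extreme tails). Noise is Gaussian on the M scale: a +1 M shift moves beta
by exactly `b(1−b)/(1+b)` — about 0.045 at `b = 0.05`, about 0.17 at
`b = 0.4` — and a symmetric 0.8 beta gap (0.1 vs 0.9) spans ≈ 6.3 M units,
so the benchmark's SD = 6 level drowns even the strongest markers while
SD = 1 approximates realistic array noise.

## The synthetic generator

`synth_purified_dataset` emulates a purified-leukocyte study pair:

| parameter        | default   | meaning |
|------------------|-----------|---------|
| `n_cell_types`   | 7         | blood-like design |
| `n_cpgs`         | 2000      | array down-sampled to desk scale |
| `n_dmcs_per_type`| 50        | planted markers per type |
| `delta_range`    | (0.5, 0.9)| planted beta difference vs all other types |
| `replicate_sd`   | 0.15      | M-space replicate noise (array-realistic) |
| `n_replicates`   | 6         | replicates per cell type and study |
| `study_shift_sd` | 0.3       | M-space per-CpG lab shift between studies |
| `dhs_enrichment` | 0.8       | P(planted marker lies in its type's DHS) |

Baselines are bimodal (45% near 0, 45% near 1, 10% intermediate). The
*test* study shares the underlying type means but adds a per-CpG M-space
shift common to its samples, so reference construction (train) and
evaluation (test) are independent in the way two labs' datasets are.
Background CpGs fall in some cell type's DHS at rate 0.1. Mixture weights
are C Uniform(0,1) draws normalised by their sum — deliberately the
normalised-uniform recipe, not a flat Dirichlet. Test-set mixtures are
built from the test study's per-type *mean* profiles.

What the generator does **not** emulate: Illumina probe-type chemistry and
normalisation artefacts, probe cross-hybridisation, correlated
(block-wise) noise, realistic genome geometry, or cell types missing from
the reference. Passing benchmarks therefore demonstrate correctness of the
estimators under the stated noise model, not performance on raw array
data.

## Benchmark and comparison

Per Monte-Carlo run, 100 fresh simplex-weight mixtures are built from the
test profiles; M-space noise at SD ∈ {0,…,6} is added once per level and
every method sees the identical noisy matrix. Scores are per-cell-type
RMSE and R² (squared Pearson correlation across mixtures — not
1 − SSE/SST, which can be negative; a constant estimate scores 0), plus
unweighted averages over cell types; 25 runs per level. Methods are
compared on the 25 run-level averages with a one-tailed paired Wilcoxon
signed-rank test (exact null for small tie-free samples, tie-corrected
normal approximation otherwise; zero differences dropped; all-zero
differences give p = 1). At default settings the robust estimator is the
most accurate up to moderate noise with constrained projection overtaking
at high noise — the qualitative crossover the benchmark is designed to
expose. The problem sizes above (2000 CpGs, ~300-CpG reference, 100
mixtures × 25 runs) were chosen as the package's desk-scale study design.

## EWAS adjustment

Per CpG, beta is regressed on the phenotype (ordinal-as-numeric) plus
technical covariates and, when supplied, estimated fractions; all CpGs
share one design matrix, so the fit is a single multi-response solve with
per-CpG residual variances. Two-sided t p-values for the phenotype
coefficient are BH-corrected across all tested CpGs (no genomic-control
inflation adjustment). Fractions plus an intercept are collinear whenever
the fractions sum to one, so one cell type is dropped — by default the
one with the smallest mean fraction, which in whole blood is typically a
near-zero component. Gold-standard scoring: sensitivity = recovered
fraction of the true-positive list, specificity = 1 − called fraction of
the true-negative list, empirical FDR = true-negative fraction of the
call set (0 when nothing is called).

## Numerical choices and edge cases

* Matrix loads drop rows with any missing value (logged count); all
  downstream algebra assumes complete matrices.
* Rank deficiency of the reference raises, naming the collinear columns
  (pivoted QR).
* Zero-MAD residuals (exact fits) stop the IRLS with a warning, returning
  the current (least-squares) iterate.
* An all-non-positive raw weight vector yields an all-zero fraction row
  flagged as degenerate rather than a division by zero.
* CP output is clipped of solver dust (negative values above −1e−9 and
  sum overshoot below 1e−8).
* BH q-values are computed by the standard step-up procedure and verified
  against the literal definition on random vectors.

## Known limitations

* The moderated-t prior fit assumes enough CpGs to estimate moments of
  `log s²`; with degenerate variances it falls back to the ordinary t.
* SVR coefficients ignore the fitted intercept by design; on data far from
  the epsilon tube this makes SVR the least accurate method at high noise.
* The pairwise reference recipe requires markers with near-binary
  contrast (delta > 0.9) and finds none when cell types are similar.
* R² of a constant estimator is defined as 0, which slightly penalises
  methods that collapse to a single vertex under extreme noise.
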