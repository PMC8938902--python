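# Methods

This note documents the models, estimators and design choices in `somarsa`:
what the synthetic somatotopy generator does and does not emulate, how the
GLM and the crossnobis estimator are defined, how regions, bands and the
group statistics work, and the numerical conventions that make results
reproducible.

## The generative model

### Cortical sheet

S1 is reduced to a one-dimensional sheet of `P` voxels spaced evenly along
the medio-lateral axis of length `L` (defaults `P = 1500`, `L = 62.7` mm).
A 1-D geometry is sufficient because every spatial operation in the analysis
— anatomical masks, winner-takes-all ROIs, equal-height bands — is an
interval operation along this axis; the analysis itself treats the strip as
one-dimensional.

Each condition `c` of a task contributes two signal components to the
noise-free response amplitude of voxel `x`:

* **Mean map** (classical somatotopy):
  `m_c(x) = a · exp(−(x − μ_c)² / (2σ²))`, a Gaussian bump at the
  condition's body-part zone centre `μ_c` with tuning width `σ = 4` mm and
  peak amplitude `a = 3` (arbitrary response units — the units of GLM
  betas). Zone centres sit at 15% (feet), 50% (hand) and 85% (lips) of the
  strip; face subparts tile the lateral zone and digits D1–D5 the central
  zone in their anatomical order.
* **Distributed pattern** (information without activation):
  a mean-free voxel pattern `ε · g_c(x)` of amplitude `ε = 0.3` present
  across the *whole* sheet. Patterns of subparts at cortical rank distance
  `k` correlate as `ρ^k` (default `ρ = 0.6`), generated by an AR(1) chain
  across subpart rank; this single assumption produces the topographic
  gradient (adjacent subparts more similar than non-adjacent) everywhere on
  the sheet. Patterns are mean-centred per condition, so they add no
  univariate signal.

For the body task, each condition is a (body part, action) pair. Its
pattern is `ε · g_part + a_act · h_action` with `a_act = 0.3`, where the
action patterns `h_squeeze`, `h_push` are mean-free and *shared across body
parts*. Consequently same-action part pairs differ only through part
patterns (the distance the body-part analysis measures), two actions of the
same part are discriminable anywhere on the sheet, and setting the pattern
amplitudes to zero is a complete negative control for multivariate
information. The cost is that no part×action interaction exists in the
simulant — a deliberate simplification.

### Noise

Scanner noise is Gaussian with three structured components, all per
subject-hemisphere:

* **heteroscedasticity**: per-voxel noise sd drawn uniformly from
  `voxel_sd_range = (0.7, 1.3)`, scaled by `scanner_sd` — this is what makes
  multivariate noise normalization do real work (noisy voxels must be
  down-weighted);
* **spatial correlation**: a squared-exponential kernel of length scale
  `spatial_kernel_mm = 1.5` carrying `spatial_mix = 75%` of the variance,
  the remaining 25% being white thermal noise. The white floor is
  physically standard and keeps the spatial covariance well conditioned (a
  pure smooth kernel on a dense grid is numerically singular);
* **temporal AR(1)**: lag-1 autocorrelation `φ = 0.3`, applied so that the
  stationary spatial covariance equals the analytic form
  `Σ = scanner_sd² · D K D` exposed as `CorticalSheet.true_noise_cov`, the
  oracle for recovery tests.

Smooth-field samples are drawn from a truncated eigenbasis of the kernel
(cached per geometry; truncation at a 1e-7 relative eigenvalue keeps the
factorization accurate to ~3e-4 per matrix entry, far below the sampling
error of any covariance estimate in the pipeline).

`scanner_sd = 3.5` calibrates the overall signal-to-noise so that the
default pipeline lands in a realistic regime:
primary-ROI univariate z levels around 5–6 (clearly significant but not
saturated at the z = 8.2 clip) and group-level dissimilarity t values in
the 5–50 range at n = 22. No effect magnitudes in generative units are
available to calibrate against, so amplitudes target the qualitative result
pattern only, not at any particular empirical t values.

### Session structure

Timing follows the emulated protocol: TR 1.45 s throughout; body task 6
conditions × 8 s blocks × 4 blocks/run, 5 rest blocks, 4 runs of 216
volumes; face task 4 conditions, 3 runs of 172 volumes; finger task 5
digits × 9 s blocks, 4 runs of 346 volumes; body-part localizer (toes,
hand, lips) 12 s blocks × 4 repeats, one run. Block orders are
counterbalanced to first order: a seeded greedy packer with restarts makes
every ordered condition transition count equal within ±1 across the
session, with no immediate repeats. Rest blocks and residual run time are
distributed as evenly spaced gaps. Runs are simulated for one hemisphere
(body) or two independent hemispheres (face/fingers, which are analysed
bilaterally).

All randomness flows from one master seed through
`numpy.random.SeedSequence` spawning (subject → hemisphere → sheet /
sequence / noise), recorded in the cohort manifest; regeneration is
bit-identical.

### What the generator does not emulate

Head motion, field inhomogeneity, cortical folding and surface geometry,
atlas uncertainty, physiological nuisance structure beyond AR(1)+smooth
noise, part×action interactions, and any systematic hemisphere difference.
Passing tests therefore show that the *estimators and inference chain*
behave correctly under the stated statistical structure — not that real
cortex contains distributed information, which is an empirical question no
simulator can settle.

## GLM

Each condition's boxcar is convolved with a canonical double-gamma HRF
(peak delay 6 s, undershoot 16 s, peak:undershoot 6, dispersion 1 s;
kernel scaled to max 1) on a 10× oversampled grid and sampled at volume
times; regressors are normalized so an isolated block peaks at 1, making
betas read as plateau amplitudes in the generator's units. Temporal
derivatives are included as regressors but weighted zero in contrasts.
Drift is modelled inside the GLM as a discrete-cosine basis with
frequencies up to 1/cutoff (cutoffs 150/119/150 s per task, 280 s for the
localizer) — equivalent in purpose to a high-pass filter but exactly
reproducible. Estimation is voxel-wise OLS per run; run effects combine
within subject by fixed effects (mean effect, mean variance / number of
runs, summed dof). z maps are the signed normal quantile of the t
cumulative probability, computed in log space and clipped at |z| = 8.2.
No prewhitened (GLS) time-series estimation is attempted; temporal
autocorrelation is left to inflate residual variance homogeneously, and
spatial noise structure is handled downstream.

## Crossnobis RSA

The voxel noise covariance is the run-averaged residual covariance
`Σ̂ = mean_m(R_m'R_m / dof_m)` shrunk toward its *diagonal*,
`Σ̂_λ = (1−λ)Σ̂ + λ diag(Σ̂)`, with λ chosen by a Schäfer–Strimmer-style
analytic formula on the pooled residual rows (clipped to [0, 1]). The
diagonal target (rather than a scaled identity) preserves voxel-specific
down-weighting while guaranteeing positive definiteness when voxels exceed
residual dof. Patterns are prewhitened by the symmetric inverse square
root of `Σ̂_λ`.

The crossnobis distance cross-validates the pattern-difference inner
product over all ordered pairs of distinct runs and divides by the voxel
count, so values are comparable between 50-voxel ROIs and variable-size
bands:

`d_ij = [Σ_{m≠n} δ_ij,m · δ_ij,n] / (M(M−1)P)`, `δ_ij,m = b_i,m − b_j,m`.

The implementation uses the algebraic identity
`Σ_{m≠n} δ_m·δ_n = ‖Σ_m δ_m‖² − Σ_m ‖δ_m‖²` and is tested to 1e-10
against an explicit double-loop oracle. Unbiasedness (expected zero under
the null) is verified by Monte-Carlo; negative values are retained in all
statistics and rectified only for the Torgerson MDS visualization (double
centring, eigendecomposition, per-axis sign fixed by the first condition's
coordinate).

Reductions over RDM cells are arithmetic means: same-action condition pairs
averaged across actions to give body-part dissimilarities; the two
within-part action cells per part; adjacent (consecutive in cortical order)
versus non-adjacent subpart pair classes; hemisphere averaging.

A numerical note on recovery testing: the vanishing-noise convergence of
`d_ij` to the ground-truth whitened distance is checked under white
heteroscedastic noise. With the smooth spatial kernel the true covariance
is nearly singular, and whitening along its trailing eigendirections
amplifies float error in estimate and oracle alike — the comparison, not
the estimator, becomes ill-conditioned.

## Regions, bands, peaks

Anatomical masks are axis intervals supplied by the generator's geometry: a
16 mm hand interval centred on the strip midpoint with 1 cm gaps to the
medial and lateral masks. ROIs are winner-takes-all: the `K = 50` voxels
with the highest vs-all-others localizer z inside the matching mask, ties
broken toward the lower voxel index, returned sorted — fully deterministic.

Band analysis segments the strip into 30 equal-height half-open bands
(last band closed; 2.0911 mm at the default strip length). Bands with
fewer than `min_voxels = 5` voxels are excluded and reported — real
surface-projected strips typically lose an end band this way, though the
dense default sheet excludes nothing. Per band
the univariate levels and the crossnobis RDM are computed exactly as for
ROIs, with a per-band noise covariance. Peak detection on a group-mean
band curve takes the global maximum plus any local maximum (strictly
greater than both retained neighbours) at ≥ 90% of the global maximum —
the threshold is a config knob; 0.9 is chosen so that secondary peaks of
comparable height (e.g. a double hand peak) are tested rather than
silently dropped.

## Group inference

One-sample and paired comparisons pass a Shapiro–Wilk gate at p < 0.05; on
failure the Wilcoxon signed-rank test substitutes for the t-test (exact
null distribution up to n = 25 when free of zeros/ties, else the normal
approximation with continuity correction). Activity levels are tested
two-tailed, dissimilarities and absolute level differences one-tailed
(negative dissimilarities represent noise), each family Bonferroni
corrected (reported alphas rounded to three decimals — 0.017, 0.013, 0.010
— decisions taken on the unrounded value); p below twice the corrected
alpha flags a trend. Cohen's d is mean/sd with a confidence interval from
noncentral-t inversion (one-sided intervals `[x, ∞)` for one-tailed
tests). Zero-variance inputs return a degenerate flag and no decision.

The repeated-measures ANOVA handles fully-within factorial designs of any
order via orthonormal effect contrasts (Kronecker products of normalized
Helmert matrices), with each effect's error term its interaction with
subjects; this reproduces the classical sums of squares exactly (verified
against a direct cell-total oracle and statsmodels' AnovaRM).
Greenhouse–Geisser epsilon is `tr(M)²/(d·ΣM²)` for the effect-contrast
covariance `M`, clipped to `[1/d, 1]`; two-level effects have ε = 1
identically. Hemisphere averaging for the bilateral tasks is gated by a
hemisphere × ROI × subpart rmANOVA whose outcome is recorded; averaging
proceeds regardless, with the gate outcome reported and a logged warning
when a hemisphere effect is detected.

## Reproducibility and problem sizes

Experiments are driven by a YAML-round-trippable config and one master
seed; all CSV output uses a fixed float format so identical configs yield
byte-identical files (checksummed in the manifest). The replication checks
use the default cohort sizes — 22 subjects (body/face), 19 (fingers) — at
the default sheet size. The headline-pattern check runs 20 replicate body
cohorts plus matched zero-amplitude controls; the topography power check
runs 50 finger cohorts; estimator calibration uses 1000 null subjects,
200 random oracle instances and 10000 null test draws. One caveat is
intrinsic to the headline pattern itself: requiring six true-null
univariate tests to all accept at α = 0.017 caps the per-replicate
probability near 0.90, so counts of 16–19 of 20 replicates are the
expected range even for a perfect implementation.

## Known limitations

* The 1-D sheet cannot express medio-lateral × antero-posterior structure
  (e.g. the BA3a/3b/1/2 gradient) or genuinely 2-D band geometry.
* Distributed information is stationary across the sheet; real information
  content presumably varies spatially in amplitude and code.
* The GLM ignores temporal autocorrelation in estimation (valid but mildly
  inefficient; fixed-effects t values are slightly optimistic at high φ).
* Shrinkage intensity is estimated on pooled residual rows, ignoring the
  small per-run mean constraint; at the pipeline's residual sample sizes
  the effect is negligible.
* The Wilcoxon path reports the signed-rank statistic, which is not
  directly comparable across n; effect sizes remain Cohen's d computed on
  the raw values.
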