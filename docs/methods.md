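# Methods

This note documents the statistical model, the tunable parameters, the
synthetic-data generator and the numerical choices behind `rehoseed`.

## Pipeline model and assumptions

The package assumes its 4D inputs are already motion-corrected,
spatially normalized to a common grid and free of large nuisance
structure; it performs no realignment, registration or nuisance
regression of its own. Analysis is restricted to a user-supplied brain
mask, further reduced by voxels with non-finite or constant time
courses (ranks and correlations are undefined there; the dropped count
is logged).

**Temporal filtering.** Each voxel series is bandpassed to
0.01–0.08 Hz — the band conventionally attributed to spontaneous BOLD
fluctuation — with a zero-phase forward–backward Butterworth filter,
order 2 per pass. The filter family and order are configurable; the
repetition time is a required user input (default 2.0 s) since it
cannot be recovered from the data reliably. Series are demeaned before
and after filtering, so outputs are exactly zero-mean.

**Regional homogeneity.** ReHo is Kendall's coefficient of concordance
over the K = 27 series of a voxel's 3×3×3 neighborhood (7- and
19-voxel neighborhoods available), computed from rank sums without a
tie correction; ties receive mid-ranks. At mask edges only in-mask
neighbors enter, with the effective K substituted into the formula —
padding would fabricate signal. Neighborhoods left with fewer than two
usable series get W = 0 and a flag.

A per-subject standardization (dividing the map by its in-mask mean W)
is available but **off by default**: the normalizing mean is itself a
group-dependent quantity whenever a discriminative cluster occupies a
non-negligible fraction of the mask, and dividing by it transfers the
focal effect into every background voxel. On the 4096-voxel synthetic
grid a planted cluster is 3–9% of the mask and the leak is dramatic
(the whole background becomes "significant"); on a real ~25,000-voxel
brain where discriminative clusters are well under 1% of the mask the
standardization is harmless and conventional, and can be enabled with
`PipelineConfig(normalize_reho=True)`.

**Group testing and voting.** The group comparison is a per-voxel OLS
fit `value = β₀ + β_g·group + β_s·sex` with the t (and two-sided p) on
β_g, dof = n − 3. This is the covariate-adjusted two-sample t; note it
is *not* numerically identical to the pooled two-sample t even for a
perfectly balanced, inert covariate — the residual dof differs, so
t_adj = t_pooled·√((n−3)/(n−2)) in that limiting case. Designs in
which the covariate is confounded with group are rejected. To
stabilize selection, the test is refit once per left-one-subject-out
fold; per fold, voxels with p < 0.01 are kept, filtered to connected
components of at least 10 voxels (the per-fold cluster filter is
toggleable), and each surviving voxel earns a vote. Candidates need
strictly more than 33% of the votes. Folds whose training half would
leave a group with fewer than two members are skipped with a warning
and the vote denominator is reduced accordingly.

**Clustering.** Connected components use face adjacency (6-
connectivity, the strictest reading of "connected by their edges")
by default; 18 and 26 are available. The extent rule keeps components
of ≥ 10 voxels. Components are reported largest-first with the peak
|t| voxel and the sign of the mean t.

**Seed selection.** Up to four clusters are picked greedily by size.
A cluster is skipped when its centroid lies within 20 mm of an
already-picked centroid either directly or after mirroring the picked
centroid across the x = 0 midline, so a contralateral homolog of a
selected region is not selected again. Both the count and the radius
are configurable; fewer than the requested seeds is allowed with a
warning.

**Connectivity features and classification.** Each seed's mean time
course is Pearson-correlated with every voxel and Fisher-transformed;
correlations are clipped to |r| ≤ 1 − 1e−7 first so maps stay finite,
and zero-variance target voxels get z = 0 with a flag. Feature columns
(per family ReHo / LFC / ReHoFC, per seed, per candidate voxel) are
ordered lexicographically so PCA is bit-reproducible; combined
families are concatenated *before* a single joint PCA. Feature columns
are mean-centered by the PCA; unit-variance scaling is deliberately
not applied by default. The PC count is searched among counts whose
cumulative explained variance on the training subjects lies in
[50%, 90%], scored by stratified 5-fold CV accuracy on the training
set; ties break to the smaller count, and if no count reaches the
window the count nearest 50% is used with a warning. The classifier is
a two-class Fisher LDA: projection w = S_w⁻¹(m₁ − m₀), prediction by
nearest projected class mean with equal priors (the cohorts are
near-balanced); a singular within-class scatter receives a ridge of
1e−6·trace(S_w)/dim. A linear SVM (C = 1) sits behind the same
fit/predict surface.

**Validation.** Ten repeats of a stratified 75/25 split. In `paper`
mode, seeds and candidates are derived once from the full sample and
only the dimensionality search and classifier are validated — this
mirrors deriving a seed atlas first and validating the classifier
afterwards, and is optimistically biased. In `nested` mode the entire
feature-selection chain (ReHo voting, cluster selection, FC voting)
reruns inside every training split, so held-out subjects cannot
influence any trained component; an information-flow test perturbs
held-out subjects' volumes and asserts the training features are
bit-identical. All randomness flows from one master seed through
`numpy.random.SeedSequence`, making reports byte-reproducible.

## Synthetic cohorts

The generator emulates the structure of a two-group childhood cohort:
20 + 20 subjects (sex ratios mirroring F/M = 16/57 patients vs 34/42
controls), 172 timepoints at TR 2 s on a 16³ grid of 4 mm voxels
centered on the world origin. Voxel noise is AR(1) with coefficient
0.3, scaled to unit stationary variance. Latent signals are sums of
six random-phase sinusoids with frequencies drawn uniformly in
0.01–0.08 Hz and normalized to unit variance, so planted effects lie
inside the analysis passband by construction (the bandpass passes
≥ 80% of their energy). Each planted spherical cluster adds its
subject-specific latent scaled by a group-specific weight (default:
one cluster of radius 3 voxels ≈ 123 voxels — the scale of the largest
discriminative clusters reported for real cohorts at 4 mm — with
weight 1.0 in patients, 0.0 in controls). Each planted link adds a
seed cluster's latent to a remote sphere scaled by a group-specific
coupling (default: one 19-voxel region, coupling 0.8 vs 0.0).
Overlapping planted regions are rejected. `null_spec()` keeps the same
architecture with group-equal weights for false-positive calibration.

Ground truth exposes both the planted sphere (`reho_0`) and the
*ReHo-effect region* (`reho_0_effect`): the sphere dilated by the
3×3×3 neighborhood. Any voxel whose neighborhood overlaps the planted
sphere genuinely has elevated concordance, so an ideal ReHo detector
converges to the dilated set as noise → 0, not to the sphere — recovery
metrics should therefore be read against the effect region. At default
noise, detected clusters contain the full planted sphere and roughly
half of the halo (Jaccard ≈ 0.65–0.7 vs the effect region, ≈ 0.47 vs
the raw sphere).

What the generator does **not** emulate: hemodynamic response shape,
spatially correlated physiological noise, motion artifacts, multi-site
batch effects, anatomy-shaped masks, or any sex-linked signal. Passing
tests on these cohorts therefore demonstrate the statistical machinery
(calibration of the voting thresholds, recoverability of planted
effects, absence of information leakage), not clinical performance on
real data — headline accuracies near 100% simply reflect the strong,
clean planted effects.

## Problem sizes and runtime choices

Default tests and the acceptance script use the 16³ grid, 40 subjects
and 172 timepoints; with the vectorized rank computation a full
per-cohort analysis (ReHo maps, 40 leave-one-out t-map folds, cluster
selection, seed-wise FC voting, nested ten-repeat validation) runs in
well under a minute on one core. Calibration and recovery claims are
replicated over ten independently generated cohorts.

## Known limitations

- The two-class Fisher LDA is binary by design; multi-class subtype
  discrimination is out of scope.
- The extent rule (p < 0.01, ≥ 10 voxels) is a fixed heuristic, not a
  Monte-Carlo-calibrated familywise correction; no FDR/FWE machinery
  is provided.
- "More than 10 voxels" is read inclusively (≥ 10); the threshold is
  configurable where a stricter reading is wanted.
- The homolog-deduplication rule is geometric (mirrored-centroid
  proximity, 20 mm); an atlas-label variant would be more faithful for
  real anatomy but requires a user-supplied label volume.
- Sphere seeds are built directly on the working grid; no supersampled
  construction with resampling is attempted.
- In `paper` mode, feature selection sees the full sample; reported
  accuracies in that mode are optimistic by construction and the mode
  exists for comparability, not as the recommended protocol.
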