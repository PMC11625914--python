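# Methods

## The coupling model

Neurovascular coupling is summarized here, per subject, as the spatial
Pearson correlation between two voxel maps inside an atlas unit: a CBF map
(perfusion) and a neural-activity surrogate (ALFF, ReHo or DC). The
assumption is that in a healthy neurovascular unit, regions with stronger
low-frequency neural fluctuation amplitude also receive more perfusion, so
the within-network spatial correlation is positive; disease weakens it.
Network values pool all voxels of the network's regions — a deliberate
contract, because the pooled correlation responds to between-region mean
structure that an average of per-region R values would discard (both
constructions are asserted against each other in the tests). R values are
Fisher z-transformed (`atanh`), with |R| clipped at 1 − 1e−7 first so that
degenerate synthetic inputs (exact ±1) keep finite z. Cells from regions
with fewer than `min_voxels` (default 10) usable voxels, or zero variance,
are recorded as missing with a reason and excluded pairwise downstream,
never imputed. NaN voxels in either map are dropped pairwise before the
correlation.

## Feature maps

All maps are computed inside a common brain mask and z-scored within it
(NaN outside).

- **Band-pass 0.01–0.1 Hz** — ideal FFT-domain filter with a half-amplitude
  cosine taper of one frequency bin at each edge; DC is always removed.
  Chosen over IIR designs because it is deterministic and directly checkable
  against an independent FFT oracle, bin by bin.
- **Nuisance regression** — intercept + Friston-24 motion expansion (6
  parameters, backward first differences, squares of those 12) + WM and CSF
  mean time courses; residuals via least squares, orthogonal to every
  retained regressor. Identically-zero columns (e.g. a motionless synthetic
  subject) are dropped with a warning; genuinely collinear columns raise a
  degeneracy error that names them.
- **ALFF** — mean single-sided FFT amplitude over the in-band bins of the
  smoothed, nuisance-regressed but *unfiltered* series. Computing ALFF after
  band-passing would make the in-band amplitude depend on the filter's
  stop-band behaviour, so the unfiltered series is used; this choice is a
  configuration default, not a claim about any particular published
  pipeline.
- **ReHo** — Kendall's coefficient of concordance W of each voxel's temporal
  ranks with its 27-voxel cubic neighborhood (7/19 available), mask-aware at
  boundaries, no tie correction (ties are measure-zero on real-valued data).
  Implemented vectorized via neighborhood rank-sum convolution; equal to the
  brute-force rank formula to 1e−10.
- **Degree centrality** — count of other brain-mask voxels correlating above
  r = 0.25 (binarized degree, threshold configurable); zero-variance voxels
  are excluded from the graph and counted. Computed by chunked matrix
  products of standardized series; equal to the full correlation-matrix
  count on small instances.
- **Smoothing** — Gaussian kernel, σ = FWHM/(2√(2 ln 2)) converted to
  voxels, plain zero-padded convolution (truncation 6σ) so that the total
  sum is preserved for interior-supported volumes.

Default stage order: band-pass → smooth → nuisance regression → features →
z-score; ALFF branches off before the band-pass as described. The resolved
configuration of every run is written next to its outputs.

## CBF quantification

Single-compartment, single-PLD PCASL calibration:
CBF = 6000·λ·(PW/PD)·exp(PLD/T1b) / (2·α·T1b·(1 − exp(−τ/T1b))) in
mL/100 g/min, with defaults λ = 0.9 mL/g, T1b = 1.65 s, α = 0.85,
τ = 1.8 s (consensus single-PLD values; all overridable) and the PLD taken
from per-subject metadata. Vendor scale factors (NEX, background
suppression) are omitted: NVC is correlation-based and invariant to any
positive global scale. Voxels with non-positive proton density are excluded
and counted. Multi-PLD kinetic modelling and partial-volume correction are
out of scope.

## Statistical layer

- **Group-effect scan.** One observation per subject per column means the
  mixed-model formulation reduces to ordinary least squares with fixed
  effects; the scan fits `NVC ~ group + age + sex` per column and tests the
  group factor with a partial F (equal to t² in the two-group case, asserted
  against statsmodels). BH-FDR is applied within one matrix's columns — the
  7 networks or the regions — never pooled across matrices. Constant or
  near-empty columns are excluded from the FDR family with a count.
- **BH step-up** is implemented directly (monotone adjusted values, NaN p
  values excluded but index-preserving) and cross-checked against
  statsmodels in the tests.
- **Stratification.** 1-D k-means with k-means++ and 100 restarts at a fixed
  seed; labels ordered by centroid (most negative = VFP); monthly rate =
  centroid/12. An exhaustive contiguous-partition oracle (optimal 1-D
  k-means partitions are contiguous in sorted order) verifies exactness.
- **ROC.** AUC as Mann–Whitney U/(n₁n₂) with ties counted ½ (equal to the
  trapezoidal area of the threshold curve); CI by stratified bootstrap
  percentile (default 2000 resamples, seeded), DeLong intervals as an
  alternative. AUC is invariant to monotone transforms, so z vs raw R is
  immaterial here.
- **Summary utilities.** Pooled means and one-way ANOVA reconstructed from
  (n, mean, SD) triplets — exact for unrounded summaries (SSB from group
  means, SSW from group SDs) — plus Pearson χ² on counts and Tukey HSD
  contrasts from summaries. These let printed cohort tables be checked
  arithmetically without raw data.

## Synthetic cohort generator

The generator defines the study conditions; it emulates the *data model* of
a co-registered PCASL + resting-state study, not scanner physics or anatomy.

- **Grid and atlas.** 24×24×18 voxels at 3 mm, with a rounded-box
  superellipsoid brain mask (≈6400 voxels) — an ellipsoid cannot host the
  default 100 regions at ≥50 voxels each on this grid. Contiguous regions of
  near-equal size grow competitively from farthest-point seeds, with a
  deterministic rebalancing pass for regions pinched against the boundary;
  region ids are assigned to the 7 canonical networks in contiguous blocks.
- **BOLD model.** Per region, a unit-variance band-limited (0.01–0.1 Hz)
  signal; per voxel, a uniform loading (0.5–1.5 × scale 3) times that
  signal, plus a smoothed-random-walk motion confound mixed with per-voxel
  weights, plus white noise (SD 1). WM/CSF voxels carry no neural signal —
  physiologically sensible and what makes their mean time courses pure
  nuisance. 120 timepoints at TR 1.5 s by default (desk scale; the frequency
  band needs ≥64).
- **Planted coupling.** The subject's true ALFF pattern is the in-band
  amplitude of the noiseless signal (computed with the package's own ALFF
  estimator, so truth is exact with respect to the estimator). Within each
  network the CBF pattern is built by exact mixing,
  `ρ·A_z + √(1−ρ²)·E_z` with E orthogonalized against the z-scored ALFF
  pattern, so the planted within-network correlation is exact by
  construction. The perfusion-weighted volume is the inverse of the
  calibration formula applied to `50 + 12·pattern` mL/100 g/min over a
  constant proton density, with per-subject PLD drawn from
  {2.525, 2.025, 1.525} s (weights 30/40/3, emulating a multi-protocol
  cohort; the statistics do not model this heterogeneity — the calibration
  formula absorbs the PLD per subject).
- **Subject-level coupling truth.** Per network and group a target ρ
  (default 0.35 everywhere; patients' DMN reduced by one between-subject SD
  on the z scale), plus per-subject jitter `coupling_sd` (default 0.15) —
  without it the planted ECAS–coupling correlation would condition on a
  constant, and "a group shift of one pooled SD" would be undefined.
- **Clinical table.** Demographics drawn to match the emulated cohort's
  printed distributions (ages 60.6±9.6 vs 55.1±16, male fractions 30/48 vs
  14/32 — deliberately group-confounded, as in the real cohort, which costs
  the covariate-adjusted scan a little power). ΔALSFRS-R from the planted
  cluster's normal (centroids −41/−14/−4, SD 1.5, sizes 8/13/27 scaled);
  12-month subscores redistributed by largest remainder so they sum to the
  range-clipped total. ECAS subscores correlate `ecas_coupling_r` (default
  0.4) with the subject's true DMN coupling, clipped to their instrument
  ranges.
- **Determinism.** A single global seed fans out to per-subject and
  per-stage substreams via stable CRC hashing; identical specs produce
  byte-identical output files.

**What passing tests do and do not show.** Recovery and power results hold
for this generator's idealizations — shared grid, exact co-registration,
white noise, linear confounds, planted patterns at voxel resolution. They
do not certify performance under realistic anatomy, registration error,
physiological noise spectra, or spatial autocorrelation; in particular the
recovery studies disable spatial smoothing because smoothing genuinely
alters a voxel-scale planted pattern (on real data, where both maps are
smooth, the 6 mm default is appropriate and remains the pipeline default).

## Reproducibility studies (experiments module)

Problem sizes were chosen so the full suite runs in minutes on one CPU:

- *Recovery*: 20 cohorts × 2 subjects on the default-size grid (every
  network ≥ 500 voxels), full image path, MAE of Fisher-z coupling ≈ 0.02
  (criterion < 0.05).
- *Power and calibration*: the scan is exercised on the generator's
  subject-level coupling model directly (true Fisher-z per subject plus
  covariates, no image synthesis), because hundreds of cohorts are needed;
  the image path's extra estimation noise (SE ≈ 0.03 per network at default
  sizes) is small against the between-subject SD 0.15. The DMN detection
  rate under a one-pooled-SD shift is 0.91–0.92 (500–1000-cohort runs);
  population-level claims near a 90% boundary are asserted over 200 cohorts
  against binomial 2.5σ bounds rather than on small knife-edge samples
  (the same policy as the null ECAS-correlation check, whose true pass
  probability per seed is 0.91).
- *Stratification*: generated ΔALSFRS-R data are clustered and compared to
  both the planted labels and the exhaustive contiguous-partition optimum.

## Known limitations

- The scan assumes one observation per subject per column; repeated-measures
  designs would need an actual mixed model.
- No slice timing, realignment, spatial normalization, scrubbing, or
  partial-volume correction; inputs are assumed co-registered on one grid.
- Degree centrality is O(V²) in brain-mask voxels; fine at desk scale
  (~6400 voxels ≈ 2 s/subject), memory-chunked but not approximated.
- The generator's progression SD (1.5) makes stratification exactly
  recoverable by design; real ΔALSFRS-R spreads (~3) would produce
  occasional boundary misassignments.
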