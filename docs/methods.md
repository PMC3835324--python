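# Methods

This note documents the models, estimators and numerical choices behind
`ycquant`, and what the synthetic validation does and does not demonstrate.

## Ratio imaging and calibration

**Model.** The YC3.6 readout is the background-subtracted emission ratio
`R = (YFP − B_yfp)/(CFP − B_cfp)`, monotone in calcium through the Hill
isotherm `[Ca²⁺] = K_d ((R − R_min)/(R_max − R))^{1/n_H}` with
K_d = 277 nM, n_H = 1.1, R_min = 1.36, R_max = 2.48 (the shipped in-vivo
constants; K_d and n_H are taken as given, never re-fit). The analytic
inverse `R = (R_min + R_max x)/(1 + x)`, `x = (c/K_d)^{n_H}`, drives the
synthetic forward model; the two functions round-trip to 1e−9 relative.
Ratios at or above R_max are flagged *saturated* (the isotherm diverges; no
concentration is claimed) and excluded from concentration summaries but kept
in ratio-space statistics. Ratios below R_min map to 0 nM with a *subfloor*
flag. R_min/R_max can be re-estimated from a control population as the
medians of the `ceil(0.05 n)` smallest/largest ratios (n ≥ 40 required so
each tail holds at least two values; an even tail's median is the mean of
its central pair).

**Background.** One scalar per channel per stack, estimated as the median
voxel intensity. Fluorescent structures occupy far less than half the
volume, so the median tracks the additive offset; unlike a low percentile
(e.g. 20th), it is also unbiased under Poisson shot noise, whose 20th
percentile sits ~0.84 SD below the mean. The percentile, a fixed-value
override, and a shared-scalar mode (one background for both channels) are
config options.

**ROI ratio estimator.** The default is the ratio of background-subtracted
channel sums over the ROI's valid voxels — algebraically the
denominator-weighted mean of per-voxel ratios. The unweighted per-voxel
ratio mean (`measure_rois`, also available as `roi_method: ratio_first`)
carries a Jensen bias of order `r·Var(CFP)/E[CFP]²` per voxel, which at a
few hundred counts per voxel inflates recovered concentrations by 10–18%;
the ratio-of-sums estimator recovers rendered concentrations within ±2.5%
at the same photon budget. Voxels with non-positive subtracted CFP (no
denominator signal, tolerance `eps = 1e-6`) or negative subtracted YFP are
invalid; ROIs with zero valid voxels carry a no-signal flag and are excluded
downstream.

## Spine detection

Shafts are given as 3-D polylines with a radius (from the generator's
ground truth or user SWC files; automatic tracing is out of scope). The
detector works on the median-blurred (3-voxel kernel) merged CFP+YFP
volume:

1. **Halo suppression.** The PSF smears each bright shaft into a radially
   decaying sleeve. For every trace in the field of view the sleeve is
   estimated as the 25th-percentile intensity per 0.2 µm radial-distance
   bin (a low quantile, so sparse spines do not inflate it); the expected
   non-spine signal at a voxel is the background plus the summed
   above-background halo of all shafts. Spines are voxels whose intensity
   exceeds that expectation by more than `k (I_shaft − background)` with
   k = 0.3.
2. **Geometric gates.** Candidates must lie 0.2–3 µm outside the shaft
   surface; within 0.6 µm axially of the shaft (the axial PSF of in-vivo
   two-photon imaging cannot resolve z-projecting spines, and its axial
   smear of the shaft would otherwise mimic them — real in-vivo spine
   counting is likewise restricted to lateral protrusions); at least 0.5 µm
   of arc from the trace ends (blurred end-caps mimic spines); and closer
   to this shaft's surface than to any other's (nearest-territory rule —
   the automated counterpart of confirming a spine connects to *this*
   shaft).
3. **Instance separation.** Surviving voxels are 26-connectivity labelled,
   then watershed-split at residual-intensity peaks more than 1.6 µm apart
   laterally (a deterministic sub-milli-count ramp breaks the plateaus of
   median-filtered count data, which would otherwise yield one peak per
   tied voxel). Pairs fused below that separation show no intensity dip,
   but their footprint along the local shaft tangent stretches: a blob
   spanning ≈ two single-spine footprints counts twice and is split along
   the tangent into equal-mass halves. The single-spine reference footprint
   is the dendrite's own median region footprint (most regions are
   singles), clipped to [0.7, 1.6]× a 1.0 µm prior, because the absolute
   above-threshold footprint depends on where the scene's threshold landed.
   One detection is emitted per region at its residual-weighted centroid,
   kept if the centroid protrudes 0.2–3 µm from the surface.

Against rendered ground truth the detector recovers 12/12 spines on an
isolated high-SNR dendrite (positions within 0.5 µm) and per-group mean
densities within about −13%…−3% of the realized truth for cohorts at 0.6
(control) and 0.42 (tau) spines/µm, with near-zero false-positive rates.
The residual undercount comes from same-side pairs closer than ≈ 0.55 µm
(irresolvable at this PSF and unsplittable by footprint) and from territory
exclusions near neighbouring dendrites; because it applies equally to both
genotypes, ratios of group means (the percent-reduction estimate) are
essentially unbiased.

**Segment rules.** Density = spine count / polyline arc length. Only
segments longer than 20 µm bearing at least 3 spines are analysed
(strict >20; ties at the boundary are excluded). Each included dendrite is
paired with its own shaft ROI mean ratio; records without a ratio
measurement are dropped with a logged warning.

## Cohort statistics

Statistics run in ratio space; concentrations are derived afterwards.

- **Overload thresholds**: the 95th percentile (linear interpolation
  between order statistics) of pooled control mean ratios, separately for
  dendrites and spines; ≥ 20 control measurements per compartment required.
  Overload is a strict `>` comparison (ties are not overloaded). Thresholds
  computed from a control set flag ~5% of that set by construction, up to
  percentile discreteness. The original cohort's published thresholds
  (dendrite 2.14, spine 2.24) are shipped as reference constants
  (`REFERENCE_THRESHOLDS`); they depend on raw data not deposited and are
  not recomputed.
- **Mixed-effects logistic regression** (`overload ~ genotype + (1 |
  animal)`): structures within an animal are correlated, so the genotype
  effect is tested with a random-intercept logistic model fitted by
  maximum likelihood. The marginal likelihood's one-dimensional integrals
  use 25-node Gauss–Hermite quadrature; optimisation is L-BFGS-B over
  (β, log σ_u) with bounds |β| ≤ 20, log σ_u ∈ [−8, 3]; standard errors
  come from a central-difference Hessian (step 1e−4) and p-values are Wald
  z tests, the mixed-model convention. The fit agrees with lme4::glmer
  (nAGQ = 25) to ~1e−3 on coefficients, SEs and σ_u, and its type-I error
  under a 15-animal null simulation is 0.05. All-identical outcomes or
  diverging estimates (|β| > 15) raise a separation error rather than
  returning a silent fallback. Dendrites and spines are fitted separately.
- **Spine density**: per-animal mean density of included dendrites, then a
  two-sided Student t-test between genotypes (Welch via config);
  `percent_reduction = 100 (1 − mean_tau/mean_control)`. Shapiro–Wilk
  normality statistics for the per-animal means are reported alongside.
- **Density–calcium correlation** (tau dendrites): OLS of density on
  parent-shaft ratio (reporting R² and the slope p-value) plus Spearman's
  ρ with its p-value. Zero variance in either variable is an error.
- No multiple-testing correction is applied anywhere.

## Synthetic cohorts

The generator encodes the study conditions: 6 control and 9 tau animals,
10 volumes per animal, ~31 dendrite ROIs per volume (≈ 4650 dendrites) and
~77 spine ROIs per animal (≈ 1155 spines); control spine density
0.6 spines/µm with a 30% tau reduction and a 10% between-animal CV of
density; resting calcium i.i.d. log-normal, moment-matched to mean
125.3 nM / SD 101 nM, *identical in both genotypes* — the default encodes
spine loss without calcium change. An optional tau mixture
(`overload_fraction_tau`, high component at 3× the median) exists solely to
give the overload statistics a detectable alternative for power testing.
The 0.6 spines/µm control default is a conventional cortical pyramidal
value (the effect of interest is relative); segment lengths are 22–28 µm
rendered (21–60 µm in the statistical path), spine placement is a Poisson
count at the configured rate with positions uniform under a 0.4 µm
hard-core spacing (so counts stay exactly Poisson) and a 0.5 µm end margin.
Physical-consistency constraints keep scenes anatomically possible: traces
are resampled until ≥ 3 µm apart (dendrites cannot interpenetrate) and a
spine is placed on the side of the shaft where it actually protrudes.

**Rendering** (the physics the pipeline must undo): per structure the true
ratio r* = calcium_to_ratio(true calcium) fixes the channel split
(CFP = N/(1+r*), YFP = r*·CFP at photon budget N = 500 expected
counts/voxel), per-channel backgrounds (40, 60) are added, both channels
are convolved with a Gaussian PSF (σ = 0.6, 0.25, 0.25 µm in z, y, x) and
Poisson shot noise is drawn; voxels are 0.8 × 0.2 × 0.2 µm. Shaft radius is
0.5 µm and spine heads 0.45 µm (≈ 0.9 µm head diameter, realistic mushroom
scale and bright enough to survive PSF dilution at this budget). Noise and
PSF can be disabled individually: the noiseless, PSF-free render followed
by the measurement chain reproduces true concentrations to rounding error.
ROI label cores sit inside each structure (80% of the shaft radius, the
spine head radius) so edge blur does not contaminate ROI means.

**Statistical fast path.** Replicate studies (the 50-seed cohort recovery
and the 500-replicate type-I simulation) would gain nothing from rendering
thousands of voxel volumes, so `simulate_measurement_tables` draws per-ROI
mean ratios directly from the same ground-truth model: true calcium →
true ratio, plus Gaussian noise with the shot-noise SD of an ROI mean,
`sd = sqrt(r (1+r)² / (N n_vox))`, with effective ROI sizes of 100 voxels
(dendrites) and 20 (spines). Dendrite records for the density analysis use
8 segments per animal, mirroring the 5–10 analysed per animal in practice.
The fast path and the rendered path share every downstream column, so the
statistics code cannot tell them apart.

**What passing does and does not show.** The generator's noise is Poisson
only (no read noise, no motion, no photobleaching, no spectral
bleed-through), its PSF is Gaussian rather than a physical two-photon PSF,
calcium is at steady state (no transients), dendrites are smooth polylines
near one imaging plane, and ROI/trace definitions are exact rather than
hand-drawn. Recovery of the injected effects therefore validates the
estimators and their composition under idealised but non-trivial imaging
physics; it does not certify performance on motion-corrupted or
bleed-through-contaminated recordings, and the spine detector is a
documented surrogate for interactive NeuronStudio counting, validated
against synthetic truth rather than against that tool.

## Degenerate inputs and determinism

Empty measurement tables, constant calibration populations, all-identical
overload flags, single-animal groups, zero-variance correlations and
zero-length traces all raise typed errors naming the offending quantity;
batch conversion of an empty table returns an empty table. Every stochastic
stage takes an explicit integer seed (`numpy.random.default_rng`);
identical seeds give bit-identical scenes, stacks, tables and reports, and
dataset directories carry SHA-256 manifests so regeneration can be
verified. Replicate studies use problem sizes chosen to keep the full
validation suite around five minutes on one CPU: 50 seeds for cohort
recovery, 500 replicates for the type-I simulation, 100-replicate
normality checks, and 4-animal-per-group rendered cohorts for detector
validation.
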