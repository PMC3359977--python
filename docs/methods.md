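# Methods

This note records the models, conventions and numerical choices behind
`rpmkit`, in the order data flows through the package.

## Movement measures

All measures operate on 2D projected positions at uniform intervals
(default 1 s), reflecting thru-focus acquisition in which fluorescence is
projected along the focusing (Z) axis onto a plane. No smoothing or drift
correction is applied before measurement; speeds are per projected step
and never 3D.

**Bias.** The mean cosine of turning angles between successive
displacement vectors. Zero-length steps have no direction and are removed
before angles are formed; the effective angle count is reported as
`n_angles`. If fewer than two non-degenerate steps remain the bias is
undefined and returned as NaN rather than a number.

**Bounding-box area.** "Minimum bounding box" is taken as the
*axis-aligned* box — the simplest reading, and the default. Because an
axis-aligned box is not rotation-invariant, the orientation-independent
minimum-area rotated rectangle (rotating calipers over the convex hull) is
also implemented behind `rotated=True`; it never exceeds the axis-aligned
value. The track is tiled into consecutive windows of `window_s/dt + 1`
positions, adjacent windows sharing their boundary frame, and the per-spot
value is the mean over complete windows (`mode="first"` restricts to the
first window). A 120-frame acquisition therefore contributes exactly one
complete 60-s window (frames 0–60); a 121-frame track contributes two.
Incomplete trailing windows are never used.

**Population summaries.** The center is the median and the dispersion the
average absolute deviation from the median (AAD), since per-spot measures
are strongly non-normal. Empty strata are omitted.

## Pairing and collision trapping

Two homologous loci score **paired** when their separation is strictly
below 0.2 µm (a tie at exactly 0.2 µm scores unpaired) or when only one
spot is resolvable. The **pairing rate** is the change in percent paired
from t3 to t5 divided by 2 (percent per hour); it may be negative. A
least-squares slope over all timepoints is available
(`pairing_rate_regression`) but is not the default, and the pre-meiotic
(somatic) baseline single-spot fraction is reported, not subtracted.
Collision-trap fractions are computed after filtering to nuclei in the
earliest prophase stage (Zip1 spots present, no lines); filtering can only
reduce the cell count.

## Bouquet metrics

Stacks are preprocessed per channel by Gaussian blurring with a *physical*
sigma (default 0.15 µm), converted per axis to voxel units so anisotropic
z spacing (0.2 µm vs ~0.1 µm laterally) is always respected, followed by
thresholding that zeroes sub-threshold voxels. The threshold is Otsu per
channel by default; a fixed-quantile alternative is provided. Thresholding
precedes centroid computation. Coordinates use the voxel-center
convention: physical position = 0-based index × voxel size, per axis.

"3-dimensional variance of signal intensity" is interpreted as the **trace
of the intensity-weighted coordinate covariance** (the sum of per-axis
spatial variances). This is the only interpretation with the stated units
of µm² that grows with spatial spread; a determinant or per-axis variant
would have different units or lose isotropy. Dividing by the nucleus
radius (SPB-to-DNA centroid distance, µm) gives the dispersion in µm.
Cutoff comparisons at 0.6 are strict. Coincident SPB and DNA centroids
give radius 0 and raise an error in the normalized metrics rather than
returning infinity.

Deconvolution of the original imaging pipeline is out of scope; the
preprocessing here is Gaussian smoothing plus thresholding only.

## Synthetic generators

The generators define the test conditions for every pipeline stage; they
emulate the structure of the real data, not its exact parameter values.

**Tethered walk.** The physics of spot motion is not prescribed by the
biology at this resolution, so the simulator is the simplest model able to
reproduce the two qualitative regimes of interest: (i) raising directional
persistence at fixed step scale broadens the range of travel (area up)
while leaving the average speed essentially unchanged — the early-prophase
signature — and (ii) raising the step scale raises speed and area together.
A point constrained to a sphere of radius 1 µm takes tangential steps
whose direction mixes the previous direction (weight = `persistence` ∈
[0, 1)) with a fresh isotropic tangent, and whose length is exponential
with mean `step_scale_um`, replaced with probability `dash_prob` by an
exponential dash of mean `dash_scale_um`; the position is re-projected to
the sphere after each step. The observable is the orthographic XY
projection (no depth attenuation) plus Gaussian localization noise
truncated at ±3 s.d., so noisy positions provably stay inside the disc of
radius R + 3·σ. Dash frequency and length are placeholders — no
quantitative measurement of the occasional fast excursions at early
timepoints exists to calibrate them. Each generator call uses one RNG
stream seeded from its config; there is no global state.

`ACTIVITY_PRESETS` provides a graded series (wild_type > mps3-dCC >
mps3-dAR > ndj1 > csm4) whose 500-track median areas are strictly ordered;
only the ordering is claimed, not the experimental medians.

`isotropic_planar_tracks` is the exact null model for the bias statistic:
unconfined planar walks with i.i.d. uniform directions and exponential
step lengths, for which the expected per-track bias is exactly 0.

**Pairing time course.** True paired fraction = baseline + rate·(t −
onset), clamped to [0, 100], with baseline 20% (somatic pairing) and onset
at t3 by default; the observation is a binomial draw of `n_cells` per
timepoint (200 by default, the standard scoring depth). On an unclamped
ramp the t3/t5 difference estimator is unbiased; the acceptance suite
verifies mean error < 0.2 %/h over 10⁴ replicates at n = 200.

**Collision trap.** Two independent tethered loci per cell, initial
positions uniform on the sphere, collision when 3D separation <
`capture_radius_um` (0.2 µm). Tetramer mode is absorbing. In dimer mode a
collided pair moves jointly (following one locus' walk) and unbinds with
hazard `unpair_rate_per_s`; after unbinding the loci walk independently
from the shared point, so they remain scored as one spot until they drift
apart — a deliberate simplification of re-dissociation geometry. At
duration 0 the single-spot fraction equals the chance-overlap baseline
r²/(4R²) of independent uniform placement.

**Nucleus renderer.** 64 z-slices at 0.2 µm and a 64×64 lateral grid at
0.1 µm/pixel by default. The DNA channel is a solid sphere (radius 1 µm)
at the grid center; the SPB is a single point on the sphere surface; the
telomere channel holds `n_foci` surface points with directions drawn von
Mises–Fisher around `cluster_direction` with concentration κ (κ = 0 is
uniform; sampling uses the S² inverse-CDF method, numerically stable for
large κ). Foci default to 32 distinguishable points: the metrics are
intensity-weighted averages, insensitive to whether the full telomere
complement is resolved. Points are deposited with trilinear (sub-voxel)
weights, all channels are blurred with an isotropic physical-units
Gaussian PSF (σ = 0.15 µm), and Gaussian noise is added. Poisson shot
noise is omitted — at the tested SNR the intensity-weighted metrics are
insensitive to the noise family.

## Statistical tests

All four tests report two-sided p values. The Yates-corrected chi-square
truncates the correction at zero (tables where N/2 exceeds |ad − bc| give
χ² = 0, p = 1). The Mann-Whitney statistic is reported as min(U_a, U_b)
(documented convention; perfect separation gives 0); the p value is exact
for n ≤ 8 per group without ties and otherwise uses the tie-corrected
normal approximation with continuity correction. The KS p value uses the
asymptotic Kolmogorov distribution by default: at the sample sizes used in
population comparisons (hundreds of spots or cells) it is well calibrated,
whereas the exact small-sample null is visibly conservative there;
`method="auto"`/`"exact"` remain available. Calibration is verified over
10⁴ null replicates at α = 0.05 — KS (n = 500), MWU (n = 50) and Welch
(n = 30) reject within [0.04, 0.06] and Yates chi-square is conservative.

## Problem sizes and determinism

Verification suites use 10⁴ trajectories for null-bias and estimator-bias
checks, 500 tracks per activity preset, 50 rendered nuclei per κ on the
grid {0, 1, 4, 16, 64}, 10³ random instances per brute-force oracle
comparison (tolerance 1e-9 relative), and 10⁴ replicates per type-I-error
estimate — sizes at which sampling error is far smaller than the asserted
margins while the whole suite runs in about a minute on one core. All
stochastic tests fix seeds; every generator is bit-reproducible given its
seed.

## Known limitations

* The walk model has no polymer or hydrodynamic character: no chromosome
  arm elasticity, no motor kinetics, no nuclear deformation, no
  photobleaching. Conclusions from simulated data concern the *measures*,
  not chromosome mechanics.
* Simulated pairing time courses are synchronous; real sporulation
  cultures are not, which inflates real error bars in ways the binomial
  model does not capture.
* The renderer's PSF is an isotropic Gaussian; real widefield PSFs are
  anisotropic and structured, so absolute dispersion values are not
  transferable to real stacks — only orderings and normalized ratios are.
* The axis-aligned bounding-box convention makes the area
  orientation-dependent; cross-study comparisons should fix the
  convention (or use `rotated=True` consistently).
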