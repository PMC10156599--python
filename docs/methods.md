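# Methods

This note documents the models, estimators, numerical choices and known
limitations of `nucleoflow`. Everything quantitative stated here is
computed by the test suite or the example scripts.

## The synthetic monolayer

The generator is a phenomenological active-particle model, not a vertex or
Voronoi tissue model: the analyses it exists to validate consume only
kinematic observables (positions, velocities, nuclear areas), which this
class of model reproduces.

**Kinematics.** `n_cells` self-propelled soft disks in a periodic box.
Each cell moves at speed `self_propulsion_speed` along its heading, plus a
soft-disk repulsion (overlap-linear force, interaction radius = half the
lattice spacing, gain 0.2 min⁻¹). Headings relax toward the circular mean
of neighbours within 1.6 spacings at rate `alignment_strength` and receive
rotational noise `noise_amplitude`. Four sub-steps per stored frame;
`n_warmup` (default 20) unrecorded frames bring the system to a steady
state before recording. The `jammed` preset (speed 0.06 µm/min, no
alignment, strong noise) produces `|v_cm| ≈ 0`; the `flocking` preset
(0.3 µm/min, alignment 0.8, noise 0.15) produces `|v_cm|` comparable to
the self-propulsion speed and a correlation length of many cell sizes.
Defaults (14 µm spacing, 60 µm² nuclei, 10 min frames) mirror a confluent
mammary epithelial monolayer imaged at 0.65 µm/px.

**Nuclear areas.** The local tissue strain rate γ̇_C at each cell is the
divergence of a Gaussian-kernel-gridded velocity field sampled at the cell
— deliberately the *same estimator family* the analysis pipeline uses, so
the planted coupling is exact under the pipeline's own definition. Log-area
integrates `s·γ̇_C` with the iso-stress attenuation `s = 1/(β + (1−β)R)`,
plus an exactly discretised Ornstein–Uhlenbeck intrinsic term with
stationary sd `ou_sigma` and correlation time `ou_tau`, giving a planted
mean square strain `MSS(τ) = 2σ²(1 − e^(−τ/τ_c))`, i.e.
`γ̇₀ = 2σ²/τ_c` and `τ_c = ou_tau`. Defaults `σ = 0.10`, `τ_c = 1.5 h`
(→ `γ̇₀ ≈ 0.013 h⁻¹`) sit in the physiological range of nuclear area
fluctuations of fluidised monolayers.

**Rendering.** Nuclei are uniformly filled ellipses (area, orientation and
axis ratio from the ground truth) with PSF-smoothed edges — the erf profile
of the signed distance to the ellipse boundary, exact for a straight edge.
This matches real H2B images (flat chromatin fill, diffraction-limited
edges) far better than a Gaussian spot of the same FWHM, which at
confluent packing produces an unrealistic overlapping-tail "sea" between
nuclei. Two physical constraints are built in: the *half-maximum footprint
equals the true area*, and *each nucleus's integrated intensity is
conserved over time* (chromatin content is fixed, so a spreading nucleus
dims). The second is essential: it is what makes the integrated intensity
`J` invariant under genuine deformation but sensitive to segmentation
errors — the paper-style quality filter relies on exactly this property.
The box is rendered periodically (spots wrap) rather than cropped, so no
ground-truth nuclei are lost at the edges. A multiplicative illumination
gradient (±15 %), Poisson shot noise and Gaussian read noise complete the
image; the default photon scale puts the in-nucleus pixel SNR near 5
("moderate" SNR).

**Planted-correlation velocity field.** For validating `C_vv(r)` the
generator plants the *directional* correlation exactly: headings are a
Gaussian random surface with a linear variogram `γ(r) = 2r/L`
(k⁻³-spectrum Fourier modes, log-uniformly sampled), for which
`⟨cos Δθ⟩ = e^(−γ/2) = e^(−r/L)` identically. A Gaussian *vector* field
with exponential component covariance does not have an exponential
cosine correlation (the directional correlation of a bivariate Gaussian is
a hypergeometric function of the component correlation), and using it
biases the fitted `L_c` low by ~30 %.

## Segmentation

The chain: morphological background estimate (grey opening at 3 nuclear
diameters, computed on a 4× downsampled image for speed — the standard
rolling-ball shrink trick) subtracted with a floor at zero; 5×5 local
Wiener filter; LoG map divided by the bicubic interpolation of the
magnitude of its regional minima (equalising dim and bright nuclei);
binarisation at `k = −0.5`; hole filling; two erosions; seed blobs below
4 px or below 20 % of the 90th-percentile seed intensity discarded;
internal seeds = remaining blobs, external seed = watershed lines of the
seed map; final seeded watershed on the Sobel gradient magnitude.

Three choices deserve comment:

- **LoG scale** `σ = 0.45 ×` nuclear radius (config `log_sigma_factor`).
  The textbook blob scale `r/√2` merges adjacent nuclei at confluent
  packing (LoG minima exist for only ~87 % of nuclei there); the smaller
  scale resolves neighbours at the cost of a weaker interior response,
  which the next item repairs.
- **Hole filling before erosion.** For plateau-like (flat-topped) nuclei
  the sub-threshold LoG basin is annular — the interior response is ≈ 0 —
  so without filling, erosion fragments ring-shaped seeds into arcs and
  nuclei get split.
- **Seed intensity gate.** The minima-normalisation equalises nuclei but
  also amplifies background noise into spurious sub-threshold basins in
  empty regions; gating seeds at 20 % of the bright-seed intensity removes
  these phantom detections while tolerating ~5× brightness variation
  between nuclei.

**Measurement.** Watershed regions are refined to their half-max footprint
(largest connected component above half the region's plateau median, on
the background-flattened image): the watershed boundary sits on the
gradient ridge, which for soft-edged objects does not coincide with the
half-max contour that defines the reference area. Centroids are
intensity-weighted; orientation is the leading eigenvector of the pixel
covariance (mod π); perimeters are marching-squares contours at the half
level (sub-pixel, avoiding the pixelated-perimeter overestimate that
would bias EOP); `J` integrates the raw image over the region.

On rendered monolayers at the default confluent packing and SNR the chain
identifies 97–99 % of planted nuclei (the quoted operating range for this
method class is 90–95 %); matched centroids are sub-half-pixel RMSE at
standard density after quality filtering, with the residual tail coming
from transient partial superpositions — precisely the failure mode the
`J`-based filter was designed for.

**Linking** is globally optimal frame-to-frame assignment under a squared
displacement cost with a `max_displacement` cutoff, implemented with an
augmented (birth/death slack) cost matrix and the Hungarian algorithm —
the assignment form of the classic particle-linking problem; `memory > 0`
keeps lost tracks eligible for re-linking (default 0). On ≤ 6-particle
instances it provably equals brute-force minimal-cost matching (tested).

## PIV

Single-pass, 14 µm interrogation windows (slightly larger than the
inter-nuclear distance), 50 % overlap. Correlation is *linear* (zero-
padded) and normalised by the per-lag pixel overlap — circular correlation
biases the peak toward zero displacement — with the search capped at a
quarter window (the standard displacement budget for single-pass PIV).
Sub-pixel refinement uses the three-point *tent* (linear-peak) model
rather than a Gaussian fit: nucleus fields are plateau-textured, their
correlation peaks are triangular, and a Gaussian fit systematically
underestimates fractional shifts there (integer shifts are recovered to
< 0.05 px, fractional to < 0.1 px on rendered frames). Outliers
(|v| > `vmax`, default 5× the median speed) are replaced by the median of
their valid 8-neighbours. Divergence is central-difference in the
interior, one-sided at boundaries; boundary rows/columns are excluded
from `σ_∇`.

## Strain dynamics and the MSS fit

`MSS(τ)` averages squared normalised area increments per track, then over
tracks, with quality-flagged frames excluded pairwise. Tracks shorter than
`min_track_length` (default 10 usable frames) are excluded: transient
mis-segmentations form short spurious tracks whose squared strains
otherwise dominate the small-τ mean (MSS is a mean of squares and is
tail-sensitive). The τ grid spans integer frame lags up to 1/3 of the
observation span.

The three-parameter fit `σ_w + γ̇₀τ_c(1 − e^(−τ/τ_c))` uses relative
weighting (σ ∝ MSS): measurement noise is partly time-correlated, the
plateau is the least certain part of the curve, and the short-τ regime —
which determines the physically robust parameter γ̇₀ — is densely and
accurately sampled. With uniform weights the many plateau points drag the
fit into trading γ̇₀ against τ_c; with relative weights the full imaging
chain recovers planted γ̇₀ to within ~10 % at 500 tracks. γ̇₀
uncertainty is the sd over 10 random half-subsets of tracks.

The γ̇_N/γ̇_C pairing is time-centred: velocity fields live on
half-integer frame times, so the central-difference γ̇_N(t) is paired
with the mean of the two divergence fields bracketing frame t. The binned
coupling curve reports evenly spaced γ̇_C bins spanning the central 98 %
of the data (mean ± sd of γ̇_N, plus the in-bin mean of γ̇_C, which is
the abscissa used by the through-origin weighted slope fit — with bin
*centres* as abscissa a perfectly linear dataset would not return the
exact slope).

## Stiffness ratio

Both routes invert the same iso-stress areal composite: strain partition
`ε_C = βε_N + (1−β)ε_CY` with stress continuity `E_N ε_N = E_CY ε_CY`
gives the attenuation `s = 1/(β + (1−β)R)` and hence
`R = (1/s − β)/(1 − β)`; read in step form under an imposed area strain it
gives `R = (ε_tot/Δa − β)/(1 − β)`. The stretch convention keeps
`ε_tot = (1 + linear stretch)²` (≈ 1.49 at 22 %) as the final/initial
area ratio while `Δa` is a fractional change; the mixed convention is
preserved deliberately because the reference ratios are only reproducible
under it. `β` defaults to the mid-range of measured nuclear area
fractions (≈ 0.25 jammed, ≈ 0.2 fluidised).

## Morphology

- **EOP** uses shapely polygon area/length; validity is checked so
  self-intersecting contours raise instead of returning nonsense.
- **Rigid registration** optimises the rotation angle (bounded scalar
  search, 0.005° tolerance) of the normalised, mean-subtracted correlation
  peak, then removes the residual shift by upsampled phase correlation.
  On sharply textured images planted transforms are recovered to
  ≲ 0.1 px / 0.1°; rotation of nearly isotropic images is intrinsically
  ill-conditioned.
- **Envelope fluctuations**: 8 radial line scans, gradient-maximum edge
  localisation with 3-point parabolic refinement; the sd over time of the
  edge position is one measure per scan (10 cells × 8 scans = 80 measures
  in the reference sampling scheme). An oscillating-ring phantom with
  amplitude A returns sd ≈ A/√2 within ~10 % (edge-localisation noise and
  finite sampling account for the deficit).
- **Boundary deformation** signs each vertex's minimum distance to the
  earlier outline by containment (even-odd rule via shapely). Note that
  for polygons with corners a uniform outward dilation genuinely produces
  corner displacements of √2 × the edge displacement; the "uniform
  motion → MPD = edge displacement" intuition holds exactly only for
  smooth contours.
- **Foci counting** is an h-maxima transform (prominence > the explicit,
  never auto-tuned noise tolerance) restricted to the nucleus ROI.
- **Aspect-ratio rate** is an M-estimator line fit (Tukey bisquare,
  c = 4.685), tolerant to ≲ 20 % gross outliers.
- **MSD** is time-averaged per track; `D_app` is the through-origin slope
  over the first quartile of lags divided by 4, with a curvature
  diagnostic flagging non-diffusive data.

## Organoid rotation

Per-step rotations are Kabsch fits about the centroid; angular velocity is
the axis–angle of each step divided by the frame interval (cycles/h).
Organoids are classified rotating when the mean angular speed strictly
exceeds 0.03 cycles/h. Residual trajectories (cumulative rotation
removed, body frame of the first time point) feed the overlap parameter
`Q(τ)` — the fraction of (cell, t) pairs displaced less than `d₀`,
default half the mean nearest-neighbour distance — computed on tracked
centroids rather than on voxel intensities (the particle-based equivalent
of the intensity-overlap formulation; same physical quantity). `τ*` is
the `Q = 1/2` crossing with linear interpolation, reported as infinite
when Q never decays that far. For Brownian residuals Q matches the
closed-form 3-D Gaussian displacement probability and `τ* ∝ 1/D`
(doubling the internal diffusivity halves the relaxation time) — both
tested, as is the invariance of Q under adding a global rigid rotation.

## What the synthetic data does and does not show

The generator emulates: jammed vs flocking kinematics with density
fluctuations; areas slaved to local strain through a planted moduli ratio;
conserved-content fluorescence with PSF, illumination gradient and mixed
noise; biaxial stretch tables; rotating/static organoid clouds; Brownian
tracers. It does not emulate: cell division or extrusion, mitotic
brightness changes, photobleaching, out-of-focus light, nucleoli or
chromatin texture, neighbour-exclusion nuclear shapes, or 3-D monolayer
structure. Passing recovery tests therefore demonstrates that the
estimator chain is unbiased and correctly calibrated under realistic
noise, optics and packing — not that it is robust to every artefact of a
particular microscope.

## Problem sizes

The validation suite runs on deliberately modest problems — single FOVs of
300–500 nuclei, 12–60 frames, 5 FOVs in the recall script, 200 tracer
tracks — chosen as the smallest sizes at which the statistical tolerances
(5–20 %) are comfortably resolved; all scale linearly if more precision is
needed.
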