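# Methods

`iplorg` reconstructs depth-resolved functional responses of the inner
plexiform layer (IPL) from phase-sensitive full-field swept-source OCT
(FF-SS-OCT) volume time series, and ships a synthetic measurement generator
with known ground truth so that the whole chain is verifiable by parameter
recovery. This note describes the measurement model, the analysis, the
choices that were genuinely open, and what the synthetic experiments do and
do not show.

## Measurement model

A sequence of complex-valued OCT volumes `U(x, y, z, t)` is acquired at the
triggered volume rate `1/T = 8 Hz` (70 volumes, 8.75 s). A visual stimulus (a
projected square, continuous or square-wave flicker with duty cycle 0.5)
starts at the fifth volume, so volumes 0–3 are pre-stimulus baseline.
Stimulus-evoked swelling or shrinkage of IPL sub-layers changes the optical
path length (OPL) between a sub-layer and the tissue below the IPL by
nanometres, which appears as an interferometric phase difference

    phi = 4 pi * dl / lambda0        (double-pass reflection geometry),

i.e. 66.9 nm of OPL per radian at the 841 nm centre wavelength.

## Analysis chain

1. **Registration** (`register`). Bulk axial motion (heart-beat pulsation
   plus drift) is estimated per volume against the first baseline volume from
   the FFT cross-correlation of mean-removed intensity sub-volumes (default
   blocks 32×64×64, confidence = normalised correlation peak, threshold 0.1;
   invalid blocks are filled from their nearest valid neighbour and the block
   grid is interpolated to per-A-scan shift maps). The integer peak comes
   from the intensity correlation, which is robust to speckle decorrelation;
   the subvoxel axial refinement evaluates the *complex-field*
   cross-correlation magnitude on a 0.02-voxel grid around the peak, because
   the intensity correlation of white speckle is aliased at subvoxel lags and
   biases any interpolating fit toward whole voxels. Shifts are applied with
   the Fourier shift theorem (axial) and linear interpolation (lateral), so
   the phase rides rigidly with the structure.

2. **Segmentation** (`segment`). The lower edge of the IPL is segmented once
   on the time-averaged registered amplitude: high axial-gradient points are
   selected from a 4× coarse-grained volume (top 20 % of |gradient|),
   embedded with diffusion maps and clustered with DBSCAN, and the chosen
   cluster is interpolated to a full-resolution surface and refined to
   subvoxel precision by a quadratic fit to the axial amplitude gradient.
   The diffusion kernel combines Euclidean proximity with a penalty on steps
   leaving the locally fitted tangent plane, uses an anisotropic metric with
   depth magnified 3× (layer surfaces are laterally extended; chains of stray
   points bridging two layers are steep and get suppressed), and prunes
   affinities below e⁻⁴ so that distinct layer surfaces fall into separate
   graph components. DBSCAN fragments within 3 voxels of an anchor cluster's
   mean depth are treated as one surface; among groups covering ≥ 40 % of the
   lateral extent whose median gradient strength is ≥ 0.4 of the strongest
   group's, the deepest is the IPL lower edge. (The depth-and-strength rule
   encodes the anatomy: the vitreous interface above the IPL is stronger but
   shallower; interfaces below the inner nuclear layer are deeper but much
   weaker.)

3. **Flattening**. Every volume's A-scans are shifted axially so the
   segmented edge is planar. The pipeline rounds the flattening shifts to
   whole voxels: speckle is white in depth, so fractional band-limited
   resampling would spread sinc tails of neighbouring depths into each voxel
   and dilute band-selective differential phase by several percent, while
   whole-voxel shifts move voxels rigidly. The residual edge flatness is
   ±0.5 voxel (variance 1/12 voxel²), well inside the band geometry's
   one-voxel guard margins. Subvoxel flattening remains available
   (`flatten_volume(..., subvoxel=True)`) for applications that need exact
   planarity.

4. **Phase evaluation** (`phase`). For each lateral position, temporal
   cross-spectra `dU(t, dt) = U(t) conj(U(t+dt))` are formed at volume lags
   {1, 2, 3, 4}, summed over the two voxels of each depth band, and the band
   of interest is paired against a fixed reference band below the IPL edge
   (band offsets relative to the edge: inner −8/−7, central −5/−4, outer
   −2/−1, reference +2/+3 voxels; exact offsets are config-exposed, the
   defaults space three strata evenly through a ~10-voxel IPL). The paired
   cross-spectrum is ensemble-averaged with a circular lateral Gaussian
   (σ = 4 px), and one phase time course `phi(t)` per pixel, anchored at
   `phi(0) = 0`, is solved to be consistent with all lag entries:
   magnitude-weighted least squares on wrapped residuals, initialised with
   the cumulative sum of lag-1 phase differences and refined by Gauss–Newton
   (banded Cholesky, vectorised over pixels) until the largest update falls
   below 1e-6 rad (max. 100 iterations). Common phase (e.g. from bulk axial
   motion) cancels exactly in the band pairing. Pixels whose cross-spectrum
   magnitude vanishes are flagged NaN.

5. **Response readouts** (`response`). Per-band OPL maps are
   background-corrected by subtracting, per time point, the mean over an
   unstimulated mask ≥ 200 µm from the stimulus; time courses are mask means
   anchored to the 4-volume baseline; the steady state is the mean over the
   last 625 ms (5 volumes at 8 Hz). The centre mask is the pattern eroded by
   14 px; the edge mask is where the ensemble-smoothed edge-response
   template exceeds 0.7 of its ridge maximum (the ridge peaks a few pixels
   inside the outline). The flicker frequency-response curve collects the
   central band's centre-mask steady states over a grid of stimulation
   frequencies (default: continuous plus 1, 2, 3.3, 5, 6.7, 10, 12.5, 16.6,
   25, 33, 55 Hz — the printed frequencies plus evenly-spaced intermediate
   choices).

6. **Photometry** (`photometry`). Retinal spectral irradiance converts to
   illuminance via `Ev = 683 lm/W ∫ V(λ) Ee(λ) dλ` (CIE 1924 photopic
   V(λ), bundled at 5 nm steps, trapezoidal quadrature) and to luminance via
   `Lv = Ev D²/Ap` (dilated pupil area 50 mm², pupil–retina distance 17 mm).
   The white-LED spectrum of any given stimulator is a free parameter; a
   two-band (blue die + phosphor) model is provided for demonstrations and
   no claim is made to reproduce a particular irradiance/luminance pair.

## Synthetic data generator

The generator composes, in order: fully developed speckle (circular complex
Gaussian voxels scaled by a layered reflectivity phantom with partial-volume
blending at interfaces), per-layer AR(1) temporal decorrelation, functional
OPL phase embedding, and bulk axial motion (1.17 Hz sinusoid of 1.2 voxels
plus 0.6 voxels drift, applied as Fourier shift plus the corresponding
common interferometric phase). A laterally uniform OPL background (4 nm
pulsation + 5 nm drift of the inner retina against the sub-IPL reference)
emulates vascular/metabolic motion and must be removed by the background
correction. Every draw descends from one integer master seed.

**Phantom.** Five layers (vitreous, NFL/GCL, IPL, INL, outer retina) with
amplitude reflectivities 0.04/0.55/0.62/0.25/0.35 and a smoothly curved IPL
lower edge (tilt + ~2-voxel undulations). With the default 3.5 µm axial
pitch the ~35 µm IPL spans 10 voxels: room for three 2-voxel bands with
1-voxel gaps. OPL is injected as phase on stratum masks whose boundaries sit
at the gap-voxel centres between the measurement bands, so each band vs. the
sub-edge reference carries exactly the intended OPL and fractional
resampling tails stay inside guard margins.

**Response model.** Spatial responses are centre-surround (difference of
Gaussians, σ_centre = 10 µm, σ_surround = 20 µm — a receptive field of a few
tens of µm, at the compact end of the parafoveal range). Amplitudes are
calibrated against the canonical analysis masks on the σ = 4 px smoothed
scale, because the reported in-vivo numbers are themselves mask-averaged
readouts of ensemble-averaged maps: inner sub-layer +15 nm (centre) with an
edge readout of 25 nm; central sub-layer 10 nm edge-only under continuous
stimulation plus a full-field flicker component of 15 nm; outer sub-layer
−10 nm (the in-vivo magnitude is not quantified; −10 nm is a placeholder of
the right order) without edge enhancement by default. Temporal dynamics:
saturating exponential rise, τ = 2 s. The central sub-layer's flicker tuning
is log-Gaussian, `B(f) = exp(−ln²(f/f₀)/(2·0.35²))` with `f₀ = 13 Hz` and
`B(0) = 0`: the peak lies inside the reported 12.5–16.6 Hz optimum, is
placed so the tested 12.5 Hz grid point is decisively maximal under the
generator's own readout noise, and `B(50 Hz) < 1e-3` so 50 Hz flicker is
indistinguishable from continuous stimulation.

**Decorrelation times.** τ = 0.3 s (vitreous), 100/120/160/200 s (NFL-GCL /
IPL / INL / outer retina) — inner retina faster than outer. The absolute
scale is a readout-noise calibration, not a tissue measurement: the
Knox–Thompson phase error is a random walk whose standard deviation on
masked steady-state readouts must match the ≲1 nm scatter the in-vivo
measurements show. A desk-scale field of view has ~20× fewer independent
speckle patches inside the analysis masks than the 1 mm in-vivo pattern, so
per-voxel decorrelation must be correspondingly slower to keep the readout
signal-to-noise of the emulated study. Faster decorrelation (where the AR(1)
statistics themselves are under test) is exercised explicitly in the unit
tests.

## Problem sizes

The default grid is 160×128×64 voxels × 70 volumes (the full-size sensor
format, 640×368×512, would make one sequence tens of gigabytes; the physics
is grid-size independent). One full generate-and-analyse pass takes ~1 min
on one CPU core. The acceptance script runs the continuous and 12.5 Hz
flicker experiments and the 12-condition frequency sweep all at this grid;
the test suite uses a trimmed 7-frequency sweep and 96×80×48 grids for
integration tests.

## What passing tests show — and what they do not

Recovery of the per-sub-layer amplitudes, signs, edge enhancement and
flicker tuning on synthetic data validates the *analysis*: registration,
segmentation geometry, band pairing, consistent-phase solving, background
correction and the readout conventions, under speckle, decorrelation, bulk
motion and a drifting background. The generator does not emulate real
tissue's continuous depth gradients (its sub-layers are piecewise-constant
strata), lateral eye motion or saccades, detector shot noise, dispersion or
aberrations, or photoreceptor responses; agreement on synthetic data
therefore does not demonstrate in-vivo performance, only the correctness of
the computation the in-vivo study describes.

## Numerical choices and degenerate inputs

- Phase → OPL factor λ₀/(4π); sign such that a path increase of the band
  relative to the reference is positive.
- Gauss–Newton tolerance 1e-6 rad, ≤ 100 iterations; weights |⟨dU⟩| are
  fixed across iterations so the banded normal matrix is factorised once.
- Wrapped residuals make the solver exact for phase steps up to ±π per
  volume as long as lag 1 is present (required).
- All-zero cross-spectrum pixels → NaN phase and quality.
- Constant volumes → segmentation error (`gradient zero everywhere`);
  unregisterable pairs (no block above the confidence threshold) →
  `RegistrationError`.
- DBSCAN eps defaults to twice the median distance to the `min_pts`-th
  neighbour, fallback 0.5 for degenerate (identical) points.
- Seeds: one integer master seed; per-stage child generators from
  `SeedSequence([seed, stage])`, platform-independent.

## Known limitations

- The sub-layer strata are discrete; real IPL responses vary continuously
  with depth, and band placement relative to anatomy is the dominant
  systematic in vivo.
- The outer sub-layer amplitude (−10 nm) is an order-of-magnitude
  placeholder; only its sign is constrained by observation.
- The exact weighting and lag set of the original extended Knox–Thompson
  variant are not public; the magnitude-weighted least-squares solver here
  is a reconstruction validated against brute-force oracles, not against the
  original implementation.
- Lateral motion is estimated but the generator only produces axial motion;
  rotation/shear are out of scope.
- At the desk-scale grid the edge masks contain only a few independent
  speckle patches, so edge readouts carry ~0.5–1 nm statistical noise even
  at the calibrated decorrelation times.
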