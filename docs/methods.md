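# Methods

`heliovent` segments ventilated airspaces in hyperpolarized-gas (HP ³He)
lung MRI in three stages — statistical noise subtraction, fuzzy C-means
(FCM) ventilation clustering, and semiautomatic airway removal — and
quantifies the result as a ventilated lung volume (VLV) with standard
agreement statistics.  This note records the model, the parameter choices,
and the reasoning behind the decisions that were genuinely open.

## Image model and geometry

The input is an ordered stack of coronal 2-D magnitude-MR slices.
Conventions: 0-based `(row, col)` with row 0 superior; slices ordered
anterior→posterior; voxel volume `in_plane_mm² × (slice_thickness_mm +
slice_gap_mm)`.  Defaults are 1.8 mm in-plane, 13 mm slices, 0 mm gap, the
acquisition geometry the method targets.  (The effective thickness is
sometimes quoted as 13.13 mm for the same protocol; 13.0 mm is the default
and both are overridable — the ~1% volume difference is surfaced here
rather than silently resolved.)

## Stage 1 — noise subtraction

Background magnitude noise is Rayleigh distributed.  Each slice's
background is sampled from an automated 25 × 50 pixel box at the bottom
centre (1250 samples; columns centred, even-width ties shifted left), and
the unit-bin intensity histogram h(f) is fitted by nonlinear least squares
with the *adjusted Rayleigh* curve

    r(f) = (αf + δ) exp(−(αf + δ)² / 2σ²) / σ²,

σ > 0 the Rayleigh scale, α > 0 an intensity scaling, δ a horizontal shift.
Fitting is per slice (each slice gets its own box, fit and threshold).
The optimal threshold minimises

    ε_τ = Σ_{f<τ} g(f) + Σ_{f≥τ} r(f),       g(f) = r(f) − h(f),

over integer τ, ties to the smallest τ; the model tail sum is truncated
where the cumulative model mass reaches 1 − 1e−6.  The initial mask keeps
pixels with intensity ≥ τ.

Numerical choices worth knowing:

* The histogram is normalised to a probability mass function so that r and
  h are commensurate.  The adjusted-Rayleigh family is closed under this
  rescaling — multiplying the curve by 1/Z equals scaling (σ, α, δ) jointly
  by Z — so only the ratios σ/α and δ/α are identified by a fit to a pmf.
  All recovery tests and the phantom round-trip therefore compare σ/α.
* With g taken signed, exactly as defined, ε_τ telescopes to
  (total model mass) − (empirical CDF below τ): the argmin always sits one
  bin above the largest sampled background intensity.  That is a perfectly
  serviceable threshold (just above all observed noise) and is the default;
  a `clamp_g` flag restricts g to its positive part instead.
* Least-squares initialisation: σ₀ = histogram mode, α₀ = 1, δ₀ = 0; bounds
  σ, α ≥ 1e−6, δ free.  The fit is deterministic given its initialisation.
* Histograms with fewer than three populated bins are rejected (degenerate).
* Refitting histograms of 1250 draws (the box size) recovers σ with ~2%
  median error over 20 seeds.  When continuous draws are integer-binned and
  clipped at zero (δ > 0), the refit carries a systematic ~8% bias; the
  corresponding round-trip test uses a 10% tolerance fixed from that
  pre-measured protocol.

## Stage 2 — ventilation clustering

Intensities of the pixels inside the union of per-slice initial masks
(volume-level; whole-image clustering is a flag) are partitioned into
C = 4 classes — negligible, low, intermediate, high ventilation — by FCM
with fuzziness m = 2 on the 1-D intensity axis:

    u_ik = 1 / Σ_j (D_ik/D_jk)^{2/(m−1)},  D_ik = |x_k − c_i|,
    c_i  = Σ_k u_ik^m x_k / Σ_k u_ik^m,
    J_m  = Σ_i Σ_k u_ik^m D_ik².

The recorded objective uses the squared distance: that is the quantity the
alternating updates provably decrease, and it makes the objective trace
non-increasing by construction.  Iteration stops when the largest
membership change falls below ε = 1e−5 (or 100 sweeps).  Zero-distance
pixels receive singleton memberships.  Final centres are sorted ascending
and named negligible < low < intermediate < high; negligible pixels are
returned to the background.  Masked-domain clustering is the default
because the negligible class is only meaningful among above-threshold
pixels.

Random centre initialisation (uniform over the observed range) can land in
a poor local minimum — e.g. two centres splitting the brightest mode while
negligible and low merge, with J_m several-fold above the good optimum.
Five deterministic restarts are run and the lowest-objective solution kept
(`n_init=5`; set 1 for single-run behaviour).  A hard-assignment K-means
backend with the same cost function and interface is selectable and agrees
with hardened FCM on separated data.

## Stage 3 — airway removal

The trachea and main-stem bronchi hold a large share of the gas bolus but
exchange none of it, so they are excised slice by slice.  Inputs per slice:
a user seed pixel inside the trachea and a bounding box (JSON sidecar).

1. **Seeded region growing** (Adams–Bischof) on the grayscale image,
   restricted to the box: repeatedly admit the frontier pixel minimising
   δ(z) = |g(z) − mean(region)|, updating the running mean, until the
   frontier empties or min δ(z) exceeds `stop_delta`.  Ties break by
   (row, col); growth is 4-connected (conservative against diagonal
   leaks); the result is deterministic.  No stopping rule is canonical for
   a nearly homogeneous trachea; the default is
   `max(0.2 × seed gray value, 2σ̂)` with σ̂ the slice's fitted noise
   scale — generous for a homogeneous bright tube, far below the
   tube-to-background contrast.  Growing on the binary mask instead is a
   flag.
2. **Isolation**: keep the component containing the seed, then an area
   filter removes connected areas of fewer than 50 pixels (8-connected,
   strict "fewer than": a 50-pixel component survives).
3. **Binary subtraction** of the grown airway from the ventilation mask.
4. **Templated morphology**: disk erosion (radius 2 px ≈ 3.6 mm; the
   radius is not canonical and is config-exposed), the 50-pixel area
   filter, then disk dilation — applied only inside a template box centred
   on the mask centroid with half-extents W/4 horizontally and H/2
   vertically (W, H the mask's per-slice extent), rounded outward and
   clipped.  This targets weakly connected bronchial residue near the
   mediastinum while leaving the lung periphery untouched.  The template is
   read as *half*-extents ("one-quarter of the width … from the centroid");
   the full-extent reading would halve the box.  Erosion and dilation see
   the full raster but write only inside the box, so the box edge adds no
   artificial boundary; out-of-raster pixels count as background, matching
   the literal Minkowski definitions A⊕B = {a+b} and A⊖B = {c | B_c ⊆ A}.

Slices with no seed specification pass through step 4 only.  Because the
dilation writes inside the template, it may re-add a thin band where the
template edge crosses the lung boundary; it never re-adds airway pixels
(asserted on phantoms), and the total mask never grows.

## Quantification

VLV = pixel count × voxel volume.  Agreement between two segmentations:
Dice 2|A∩B|/(|A|+|B|) (both-empty defined as 1), Bland–Altman mean
difference ± 1.96 SD (sample SD, n−1 throughout), Pearson correlation with
OLS regression (volume on the spirometric measure), and paired/unpaired
two-sided t-tests.  Identical paired vectors report t = 0, p = 1;
zero-variance differences are flagged degenerate rather than silently
producing infinities.

The package ships the ten-subject reference cohort tables (four healthy,
six asthmatic; spirometry, per-subject semiautomatic and manual VLVs, and
Dice) in `heliovent.cohort`; the statistics layer reproduces the published
group summaries from them to printed precision.

## Synthetic phantom

`heliovent.phantom` generates the only full-pipeline test data: 10 coronal
256² slices (1.8 mm / 13 mm), two elliptical lungs tapering with depth,
four concentric intensity classes with area fractions (0.1, 0.3, 0.3, 0.3),
Gaussian signal jitter, optional non-overlapping zero-signal defect disks,
a bright trachea tube with bronchial stubs on the four middle slices
(≥ 2 px clear of the lungs), and background drawn i.i.d. from the adjusted
Rayleigh model by inverse transform f = max(0, (σ√(−2 ln U) − δ)/α).
Everything is reproducible from one seed, and ground-truth lung, airway and
class-label volumes accompany each phantom.

Presets fix the study conditions at three SNR tiers: `easy` (levels
45/90/150/210, jitter 2, σ = 5, no defects), `realistic` (same levels,
jitter 5, σ = 10, 3 defects), `hard` (30/60/110/180, jitter 10, σ = 20,
5 defects; completion is asserted, recovery only reported).  The presets
place the negligible class as a faint mode just above the noise floor —
in real ventilation images that class is weak signal, not literal
background; were it at intensity 0 it would vanish below the threshold and
the four-class structure the method assumes would not exist in the data.

What the phantom does *not* emulate: coil-sensitivity shading,
partial-volume edges, Rician signal noise (available as an option, off by
default since the background model is the object of interest), anatomical
airway trees, or gas-flow physics.  Passing the phantom suite shows the
pipeline recovers a known intensity-class structure under the stated noise
model; it does not certify performance on clinical images.

## Degenerate inputs and determinism

Empty masks pass through morphology unchanged; empty∩empty Dice is 1 and
documented; constant background boxes reject the fit (< 3 bins); duplicate
FCM centres re-initialise at most five times before failing; all
randomness flows through explicit integer seeds, and identical inputs plus
configuration yield bit-identical masks.

## Problem sizes

The validation suite runs phantoms at the native 10 × 256 × 256 geometry
(one pipeline run ≈ 1 s); parameter-recovery protocols use 20 seeded
repetitions at the 1250-sample box size; FCM invariants are checked over
50 seeded runs of 160-point samples; morphology oracles enumerate rasters
up to 16–32² where literal set arithmetic is exhaustive.

## Known limitations

* The slice-level results reported for the original clinical cohort
  (109 slices) are not reproducible here: the HP ³He images were never
  deposited.  Only the printed per-subject tables can be recomputed.
* The signed-g threshold ignores the fitted curve (see Stage 1); the fit
  still matters for the region-growing stopping rule and for phantom QC.
* Thick (13 mm) slices make the VLV sensitive to the slice-thickness
  convention; compare volumes only within one convention.
* The airway stage is semiautomatic by design: seed and box quality bound
  its accuracy, and no automatic airway detection is attempted.
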