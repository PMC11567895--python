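# Methods

This note documents the models, conventions and numerical choices behind
`chromring`, and what the synthetic-scene tests do and do not establish
about real microscopy data.

## Radial chromatin profiling

A single-nucleus chromatin profile (SNCP) is computed from a 2D
central-plane image, a nucleus mask and a nucleolus-centre annotation:

1. The nucleus contour is the ordered perimeter-pixel polygon of the mask
   (Moore-neighbour tracing). One ray is cast per contour pixel, so ray
   density scales with nucleus size exactly as the contour does.
2. Intensities are sampled along each ray by bilinear interpolation at a
   0.5 px step, with the final sample exactly at the contour pixel.
3. Each ray's sample distances are divided by that ray's length, mapping
   the nucleolus centre to 0% and the contour to 100%. This makes profiles
   comparable across nuclei of different sizes and shapes.
4. All samples of all rays are pooled into twenty 5%-wide bins and averaged
   per bin; the binned profile is divided by its maximum.

Conventions that the underlying procedure leaves open, fixed here:

- **Bin intervals** are half-open [lower, upper), with the last bin closed
  at 100%, so every sample lands in exactly one bin (property-tested).
- **Pooled vs per-ray averaging**: by default all samples are pooled before
  the per-bin mean; a `per_ray` variant (bin each ray, then average rays)
  is available. On radially symmetric nuclei the two coincide.
- **Empty bins** (possible for very small nuclei, where the 5% bin width
  falls below the 0.5 px sampling step) are filled by linear interpolation
  from neighbouring bins and flagged in the profile.
- **Condition averages** carry a 95% band of 1.96·SD/√n (normal
  approximation; at the cohort sizes this package targets, n ≈ 20–70
  nuclei, the difference from a t-quantile is negligible). n = 1 yields a
  zero band and a warning.
- **Coordinates** are 0-based voxel indices in (z, y, x) order throughout.
- The central plane of a 3D mask is the z of its voxel centroid, rounded;
  an exact half rounds toward lower z for determinism.

An absolute-distance variant re-expresses each sample in µm beyond the
ray's nucleolar-edge crossing (0.25 µm bins by default), with rays that
never exit the nucleolus excluded with a warning. The resolution filter
drops rays whose nucleolar-edge-to-contour span is below a threshold
(default 9 px, the muscle-nucleus resolvability limit — see below).

## Two-ring model

SNCPs are fitted with B + A_i exp(−(x−x_i)²/2σ_i²) + A_o exp(−(x−x_o)²/2σ_o²)
by bounded least squares (`scipy.optimize.curve_fit`, trust-region
reflective). Bounds: A_i, A_o, B ∈ [0, max(SNCP)]; x_i, x_o within ±5
percentage points of their initial guesses; σ_i, σ_o ∈ (0, 100)%. The loss
is unweighted over the 20 bins.

**Initialisation** (a deliberate design choice — the centre bounds make the
fit local, so the start matters): peak centres start at the two largest
local maxima of the profile, the smaller-distance one seeding the inner
peak; a plateau of equal values counts as one maximum (its centre index).
If fewer than two distinct maxima exist, fixed starts at 25% and 90% are
used. Widths start at 8%, amplitudes at the profile value above background
at each start, background at the profile minimum. The fit is fully
deterministic. After fitting, peaks are relabelled if needed so x_i < x_o.

On noiseless profiles generated inside the bounds this initializer recovers
all 7 parameters with median absolute error far below 10⁻³ (the inverse
problem is exact); at the generator's default noise, fitted ring centres
stay within 5 percentage points of truth and the cohort-mean A_o/A_i within
10% of the generating ratio.

**Resolution limit.** Approximating the Airy pattern by a Gaussian, the
minimum resolvable separation of the two rings is d = 1.45 σ_io + 2 Δx_e
(voxels), with σ_io the mean of the two fitted widths and Δx_e the mean
offset between the fitted peak centres and their anatomical landmarks
(nucleolar edge for the inner ring, nuclear contour for the outer).
Fit-space percentages are converted to voxels via the nucleus's mean ray
length.

**Organization categories.** The two-rings / partial / single-peak call is
a rule-based classifier (the corresponding visual scoring is inherently
subjective, so the rules here are explicit and configurable, not a claim
about how any particular dataset was scored): `single_peak` if either
amplitude is below `amp_fraction` (default 0.25) of the profile maximum
above background; otherwise `two_rings` if the peak separation in voxels
reaches the resolution limit d, else `partial`. Thresholds are returned
with every call.

## Nucleolar volumetry and FISH

Detection: 3D Gaussian smoothing at σ = 0.75 voxel, automatic thresholding
(Yen or Li, computed on in-mask intensities), 3D connected-component
labelling with 26-connectivity, components restricted to the search mask.
`auto` tries Yen first and falls back to Li when Yen finds nothing or more
than five components — a deterministic surrogate for choosing the
best-suited algorithm per experiment. On the synthetic scenes (one compact
bright nucleolus over a dark background) Yen is almost always selected; Li
places its threshold near the background mode on such sparse-foreground
images and can segment most of the nucleus.

The selected object is quantified by fitting a separable 3D Gaussian
A·g(x)g(y)g(z)+B to the **raw** (unsmoothed) voxel intensities inside its
mask — smoothing is for detection only and would inflate the widths.
Initialisation: intensity-weighted centroid and second moments; fits are
done in voxel coordinates, and the ellipsoid volume V = (4/3)π σ_z σ_y σ_x
is reported in voxel³ and (via the voxel pitches) µm³. Because the fit sees
raw data, the volume is invariant to the detection smoothing sigma on
noiseless scenes; with shot noise, different thresholds change the fitted
support and the background/width trade-off moves volumes by up to ~10%,
which is the dominant error term in the recovery benchmark.

FISH signal is the sum of raw voxel values over the segmented objects minus
(voxel count × median of in-nucleus, non-spot pixels at the central
slice). The median makes the correction robust to the spot's own tails; the
corrected sum is invariant to a uniform offset of the stack up to median
granularity. Recovery of a known injected Gaussian integral is accurate to
a few percent provided the threshold sits well below the peak (the
segmented region then captures >95% of the integral); it degrades if the
threshold climbs past ~2% of the spot amplitude.

## Positioning assays and statistics

- **Three-zone assay**: boundaries R√(2/3) and R√(1/3) partition the
  nuclear disc (at the plane where the locus is brightest) into three
  equal-area concentric zones; zone 1 is the most peripheral, and boundary
  ties go to the more peripheral zone. **Decile assay**: the relative
  nucleolar-edge-to-periphery position is binned [0,0.1)→0 … [0.9,1]→9;
  spots inside the nucleolus are flagged, not binned. Zone tables are
  compared with Pearson chi-squared tests (no continuity correction,
  df = k−1).
- **Profile comparison**: per-bin statistic |mean_A − mean_B| with
  nucleus-level condition labels permuted (nuclei are the exchangeable
  units; the seeded Monte-Carlo p uses the add-one estimator
  (1+exceedances)/(1+n_perm), so p ≥ 1/(n_perm+1) and never 0). An exact
  enumeration mode covers tiny designs. Default n_perm = 10,000; the
  calibration benchmark uses 999.
- **Multiplicity**: Bonferroni with m = 20 (all bins, the conservative
  choice; configurable). Adjusted p-values are combined per region —
  0–30%, 35–65%, 70–100% of the radial distance; the bins centred at 32.5%
  and 67.5% fall in the gaps and enter no region. The default combiner is
  Fisher's −2 Σ ln p against the upper χ²(2k) tail; a complementary
  −2 Σ ln(1−p) combiner (sometimes called Pearson's method — the two names
  are often conflated) is selectable and referred to the lower tail. Both
  are monotone: decreasing any input p never increases the combined p.

## Synthetic scenes

The generator renders what the analysis assumes: a spherical nucleus with a
single, centrally positioned nucleolus, imaged with anisotropic voxels
(100 nm in xy, 200 nm between z planes), an anisotropic Gaussian PSF
(σ_xy = 80 nm, σ_z = 250 nm — diffraction-limited confocal-like values),
Poisson shot noise (default 200 photons per intensity unit) and additive
Gaussian read noise (σ = 0.02 intensity units). Intensity units are
arbitrary, as no calibration between fluorophores is assumed.

- Chromatin voxel values evaluate the ring model over normalized radius:
  the **fed** preset has a single peak (x = 0.55, σ = 0.15, B = 0.1); the
  **fasted** preset has rings at x_i = 0.25 (σ_i = 0.10, A_i = 1) and
  x_o = 0.90 (σ_o = 0.06, A_o = 0.6). These are generator defaults chosen
  to place the inner ring at the nucleolar edge and the outer at the
  periphery with a weaker outer ring; they define the benchmark conditions,
  not measured biology.
- The nucleolus channel is a 3D Gaussian, default σ = 0.8 µm in a 4 µm
  intestinal nucleus, so its half-maximum edge sits near 24% of the
  nuclear radius — consistent with the fasted inner ring position.
- Tissue size: "muscle nuclei are about a quarter of the size" is read as
  volume, so the default muscle radius scale is 0.25^(1/3) ≈ 0.63
  (hypoderm 0.8); both configurable. `preset_config` scales the nucleolar
  sigmas with the tissue factor so geometry stays self-similar.
- Cohorts jitter nuclear radii (CV 8%) with per-scene seeds spawned from a
  master seed; everything is reproducible from that one integer.
- Rendering samples voxel centres; no sub-voxel anti-aliasing. The
  nucleolus centre is not jittered by default.

What the scenes deliberately omit: multiple nuclei per field, neighbouring
tissues, autofluorescence, photobleaching, aberrated or spatially varying
PSFs, segmentation error (masks are exact by construction), and annotation
error (the nucleolus centre is exact). Passing recovery tests on these
scenes therefore validates the *measurement* chain — geometry,
interpolation, binning, fitting, statistics — not robustness to
segmentation or optical artefacts in real data.

## Benchmark problem sizes

The test suite fixes its own problem sizes: 100 noiseless profiles and 50
noisy scenes for fit recovery; 50 scenes for volumetry; 200 replicates of
10 + 10 small nuclei (2 µm radius, scaled nucleoli) at n_perm = 999 for
null calibration of the permutation test; 20 + 20 full-size nuclei for the
fed/fasted discrimination benchmark. Small nuclei are used where only the
statistic's calibration, not image detail, is under test.

## Known limitations

- Profiles assume a star-convex nucleus around the nucleolus centre; rays
  of strongly non-convex masks cross the boundary more than once and the
  contour point defines 100%.
- One nucleolus per nucleus; multi-nucleolar cells and intranucleolar
  substructure (vacuoles) are out of scope.
- The two-ring fit is local by design (±5% centre bounds); profiles whose
  true peaks sit far from any local maximum of the data are reported as
  converged fits at the bound, flagged via the per-parameter bound-activity
  record.
- Volumetry reports the Gaussian-ellipsoid volume, a model-based size
  proxy, not a thresholded voxel count.
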