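# chromring

Radial chromatin profiling and concentric-ring analysis of single nuclei in
fluorescence microscopy z-stacks.

In well-fed *C. elegans* larvae, chromatin (e.g. HIS-72/H3.3–GFP or
Hoechst-stained DNA) fills the nucleus with a single broad mid-radius
maximum. Under fasting — or when mTORC1 signalling or RNA polymerase I
activity is inhibited — intestinal chromatin reorganizes into **two
concentric rings**: an inner ring hugging the nucleolus and an outer ring at
the nuclear periphery. `chromring` implements the quantitative image
analysis that detects and measures this reorganization, for microscopists
and computational biologists who have single-nucleus z-stacks, nucleus
masks and a nucleolus-centre annotation in hand. It also ships a synthetic
scene generator with known ground truth, so every measurement can be
validated against the parameters that produced the image.

## What it computes

**Single-nucleus chromatin profile (SNCP).** From a central-plane image, a
ray is cast from the nucleolus centre to every pixel of the nucleus contour;
intensities are sampled bilinearly every 0.5 px, each ray's distances are
normalized by its centre-to-contour length (0% centre, 100% contour), all
samples are pooled into twenty 5%-wide bins, and the binned profile is
divided by its maximum.

**Two-ring model.** Each SNCP is fitted by bounded least squares with

    f(x) = B + A_i exp(−(x−x_i)²/2σ_i²) + A_o exp(−(x−x_o)²/2σ_o²)

(amplitudes and background in [0, max SNCP], centres within ±5% of their
initial guesses, widths in (0, 100)%). The ratio A_o/A_i summarizes the
relative strength of the peripheral ring. A Gaussian approximation of the
Airy disk gives the minimum resolvable peak separation
d = 1.45 σ_io + 2 Δx_e; rays whose nucleolar-edge-to-contour span falls
below it (9 px for muscle nuclei) can be excluded.

**Nucleolar volumetry.** The nucleolar marker (FIB-1–mCherry) is smoothed
(σ = 0.75 voxel), thresholded (Yen or Li), and labelled in 3D; a separable
3D Gaussian g(x)g(y)g(z)+B fitted to the raw voxels of the selected object
yields the ellipsoid volume V = (4/3)π σ_z σ_y σ_x.

**FISH quantification.** Background-corrected integrated spot intensity:
the sum over segmented voxels minus voxel count × median of in-nucleus,
non-spot pixels at the central slice.

**Positioning assays and statistics.** Three equal-area concentric zones
(boundaries R√(2/3), R√(1/3); zone 1 peripheral) and a 10-bin
nucleolar-edge-to-periphery decile assay, compared by chi-squared tests;
condition profiles are compared bin-wise by seeded permutation tests with
Bonferroni adjustment and region-combined p-values (0–30%, 35–65%, 70–100%)
via a combined-probability test.

## Worked example

```python
import chromring as cr

fed = cr.preset_config("fed")
fasted = cr.preset_config("fasted")
scenes = cr.generate_cohort(fed, fasted, n_per_condition=20, seed=1,
                            labels=("fed", "fasted"))

profiles = {"fed": [], "fasted": []}
for s in scenes:
    p = cr.profile_nucleus(s.chromatin[s.central_z], s.mask2d,
                           s.annotation[1:], condition=s.condition)
    profiles[s.condition].append(p)

fit = cr.fit_two_peaks(profiles["fasted"][0])
print(f"inner ring:  x_i = {fit.x_i:.1f}%,  sigma_i = {fit.sigma_i:.1f}%")
print(f"outer ring:  x_o = {fit.x_o:.1f}%,  sigma_o = {fit.sigma_o:.1f}%")
print(f"outer/inner amplitude ratio A_o/A_i = {cr.outer_inner_ratio(fit):.2f}")

res = cr.compare_condition_profiles(profiles["fed"], profiles["fasted"],
                                    n_perm=2000, seed=2)
for region, p in res.region_p.items():
    print(f"region {region}%: combined p = {p:.2e}")
```

prints

```
inner ring:  x_i = 23.8%,  sigma_i = 11.4%
outer ring:  x_o = 90.1%,  sigma_o = 6.3%
outer/inner amplitude ratio A_o/A_i = 0.57
region 0-30%: combined p = 1.62e-07
region 35-65%: combined p = 1.62e-07
region 70-100%: combined p = 1.62e-07
```

The first nucleus of the fasted cohort (generated with rings at 25% and 90%
and amplitude ratio 0.6) is fitted with ring centres at 23.8% and 90.1% and
a ratio of 0.57; the fed and fasted condition profiles differ significantly
in every radial region, most importantly at the nucleolar edge (0–30%) and
the nuclear periphery (70–100%) where the two rings live.

The same pipeline is available from the shell:

```sh
chromring simulate --mode fasted --n 20 --seed 1 --out scenes/
chromring profile  --bundle scenes/ --out profiles/
chromring fit      --profiles profiles/profiles.csv --out fits.csv --classify
chromring compare  --a fed_profiles.csv --b fasted_profiles.csv --n-perm 10000 --seed 1 --out cmp.csv
```

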