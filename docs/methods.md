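# Methods

## Scope and model

`stainqc` analyses grayscale images of dried-droplet drug deposits.
The working model of a deposit is radially structured: a bright
peripheral ring at the pinned contact line, a textured crown annulus
just inside the ring, and a central region carrying crystalline
aggregates. Alteration of the drug (dilution with water, admixture of
another agent) is assumed to act on three observables: the crown
thickness γ, the spatial statistics of the crown texture, and the
superficial area of the central aggregate. The package measures those
observables per image and quantifies group separation with ROC/AUC.

No physical simulation of drying, capillary or Marangoni flow, or salt
crystallization is attempted; the deposit is treated purely as an
image.

## Co-occurrence texture

The gray-level co-occurrence matrix is computed over an arbitrary
boolean region mask: an ordered pixel pair contributes only when both
endpoints are inside the mask, so irregular regions (an annulus, a
segmented deposit) are handled without rectangular cropping, and pairs
straddling the region border are discarded. Defaults follow the
reference protocol: 256 gray levels (8-bit input, no re-binning),
displacement d = 2 at φ = 0°. Conventions that the protocol leaves
open are explicit options:

- **Symmetrization** is off by default (ordered pairs, one direction);
  `symmetric=True` adds the transposed counts, the classic Haralick
  variant.
- **Entropy log base** is natural by default; base 2 is selectable.
  0·log 0 := 0.
- **Correlation** divides by σₓσ_y; on a constant region it is
  undefined and returned as NaN with a flag, never silently zero or
  dropped at the image level. Group-level ROC drops flagged values
  pairwise with a logged count.

The marginal standard deviations are square roots of the central
second moments of p(i,j)'s index marginals, which bounds the
correlation to [−1, 1].

## Segmentation and regions

Segmentation is deliberately parameter-light: the background level is
estimated as the median of the image border frame, |intensity −
background| is Otsu-thresholded, the largest connected component is
closed (disk of radius 3) and hole-filled, and a component covering
more than half the border is rejected as a failed segmentation. The
deposit radius R is the mean centroid-to-boundary distance.

Three analysis regions are derived from R: the complete deposit mask,
a center disk of radius 0.5 R, and a crown annulus at [0.6 R, 0.95 R]
by default. The fixed fractions are configuration, not inference; an
optional `auto_crown` mode instead places the annulus at the two
largest-magnitude change points of the angularly averaged radial
median-intensity profile, searched in [0.3 R, 0.97 R] so the dominant
ring/background edge at R does not capture both change points.

## Crown thickness γ

Crown-class pixels are defined photometrically: a 3-class Otsu split
of the intensities in the outer radial band [0.5 R, R]; the middle
class — between the deposit interior and the saturated ring — is the
crown. The split is accepted only when the three class means are at
least 10 gray levels apart; otherwise the band is effectively bimodal
and the stain is reported as having no crown (γ = 0, flagged), which
is the expected outcome for crown-less morphologies rather than an
error.

γ is the mean over 8 rays (starting at 0°, stepping 45°) of the radial
extent of crown-class samples, sampled every 0.5 px. Per ray, the
extent is the maximum-score contiguous interval scoring +1 for a
crown-class sample and −1 otherwise (Kadane's rule). This equals the
longest contiguous crown run when the class labelling is clean, but
tolerates the brief excursions that band-limited crown texture
produces beyond the middle intensity class; with a plain longest-run
rule those excursions split the run and bias γ low by tens of percent
at long texture correlation lengths. γ is reported normalized as
γ/γ₀, with γ₀ the mean γ of the designated control group.

## Aggregate area

Within the center disk, foreground is Otsu-thresholded; connected
components larger than 25 px are summed. A featureless center is
detected by requiring at least 10 gray levels between foreground and
background means, and reports area 0 rather than thresholding noise.

## ROC and inference

The test (altered) group is the positive class. Each feature carries a
fixed a-priori orientation (e.g. dilution lowers crown entropy, so
smaller entropy is "positive"); orientations are never flipped to fit
the data, so a feature that moves the "wrong" way reports AUC < 0.5 —
informative in itself and faithful to fixed-direction reporting.
Candidate cutoffs are midpoints between consecutive distinct pooled
values plus ∓∞ sentinels; "≥ cutoff ⇒ positive" under
greater-is-positive. The trapezoidal AUC over the empirical curve
equals the tie-corrected Mann–Whitney U/(n₀n₁) (verified to 1e−12 in
the tests against independent pair counting and
`scipy.stats.mannwhitneyu`).

The standard error is Hanley–McNeil with Q₁ = A/(2−A),
Q₂ = 2A²/(1+A); it vanishes exactly at A = 1, matching
perfect-separation reporting. The 95% limits are AUC ± 1.96·SE,
deliberately unclipped (upper limits above 1 are printed as computed).
The asymptotic p is the two-sided normal test of H₀: AUC = 0.5 using
the null SE (Hanley–McNeil at A = 0.5, ≈ 0.1036 for two groups of
16), which keeps p finite when the observed SE is 0. The optimal
operating point restricts to cutoffs with specificity > 0.5, maximizes
sensitivity + specificity, and breaks ties by highest sensitivity then
lowest cutoff; if no cutoff qualifies the unrestricted optimum is
returned with a warning flag.

Exact permutation p-values, DeLong standard errors and any
multiple-testing correction across the region × feature × group grid
are out of scope; the report carries raw asymptotic p only.

## Synthetic stains

The generator emulates only the statistical structure the analysis
relies on, not photorealism. One stain = background (level 20) +
deposit disk (90) + ring annulus (230, width 10 px) + crown annulus
(150) textured with band-limited noise + star-polygon crystals (200)
in the central disk + optional Gaussian pixel noise (sd 2), clipped
and quantized to 8 bits. Defaults: 384² image, R = 150 px, crown
thickness γ₀ = 30 px, texture correlation length ℓ₀ = 1.5 px with
amplitude sd 10 gray levels, 3 crystals totalling ≈ 5000 px.

Dilution s ∈ [0, 1] acts deterministically on the parameters:
γ ← γ₀(1 − 0.8 s), ℓ ← ℓ₀(1 + 2 s) (smoother texture ⇒ lower
co-occurrence entropy, higher energy), aggregate area ← A₀(1 + s).
The texture field is rescaled to a fixed amplitude inside the crown so
that only its spatial correlation, not its marginal histogram, varies
with s.

Within-group (stain-to-stain) variability comes from per-image
lognormal jitter: sd 0.4 on the texture correlation length and sd 0.08
on the crown thickness, plus the random texture/crystal realization.
These two jitters are the load-bearing realism choice: without them a
group's crown entropy is an almost deterministic function of γ and ℓ,
and two groups one dilution step apart separate perfectly — unlike
real deposit groups, whose replicate scatter makes ±5–10% composition
changes hard to call while ≥30% changes separate cleanly. The jitter
magnitudes were fixed, together with the response coefficients (0.8,
2, 1), to produce exactly that shape: control-vs-control AUC at
chance, a steep rise through 10–30% dilution, saturation at AUC 1 from
50%, and adjacent-dilution (Δs = 0.05) AUC below 0.75. All
coefficients are ordinary parameters and can be overridden.

The generator records ground truth as rendered (the jittered γ, the
actual painted crystal pixel count), so recovery tests measure the
analysis chain, not the jitter. Determinism is strict: one
`numpy.random.Generator` per image seeded from the per-image seed;
group seeds derive from a master seed; identical seeds give
byte-identical images.

What the generator does **not** emulate — real crystal morphologies
(dendritic, star-like, fern-like), uneven illumination, optical blur,
off-center or non-circular deposits, inter-batch drift — bounds what
passing tests show: they validate the measurement and inference chain
on deposits matching the structural model, not robustness to every
imaging condition of real micrographs.

## Problem sizes and numerical notes

The shipped analyses and tests use groups of 16 images (the reference
group size) at 384² px; the dose-response analysis covers a control
and five dilutions plus adjacent-dilution pairs, all with fixed seeds.
GLCM tests cross-check against brute-force pair enumeration on random
masked images up to 64², and against `skimage.feature.graycomatrix` on
unmasked images. Null calibration uses 1000 replicate AUCs of
identical-distribution groups of 16.

Degenerate inputs are handled explicitly: an all-constant pooled score
vector yields the two-point diagonal ROC (AUC 0.5, flagged); a mask
too thin for the displacement raises an "empty co-occurrence" error; a
blank image raises a segmentation error; γ₀ = 0 flags all normalized
thickness values rather than dividing by zero.
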