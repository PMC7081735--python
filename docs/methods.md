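# Methods

## Segmentation model

The detector treats each A-scan as a 1D depth profile I(z), z in μm from
the top (vitreous side) of the frame, and assumes three facts about rodent
B-scans: the sclera is the brightest structure; the retina is bounded below
by a sharp intensity decrease into the choroid (ORL) and above by a sharp
increase from the vitreous (IRL); and both transitions are the dominant
slope features in their respective search regions.

Detection runs in two stages per A-scan:

1. the scleral center is the argmax of the column after 2D Gaussian
   smoothing at σ = 20 μm (physical units on both axes);
2. on the axial slope of the lightly smoothed column (1D Gaussian,
   σ = 2 μm, central differences, one-sided at borders, reflective
   padding), the ORL is the first strict local minimum above the scleral
   center, and the IRL is the largest strict local maximum at depths more
   than 120 μm above the ORL.

Coarse smoothing is 2D because it stabilizes the sclera argmax against
speckle using lateral context; the slope smoothing is axial-only because the
slope is a per-A-scan depth derivative. A switch (`coarse_2d=False`) gives
the axial-only variant. "Valley" and "peak" mean strict local extrema after
collapsing runs of equal values to their midpoint index, which makes the
detector deterministic on discrete data (plateau midpoints may be
half-integral, i.e. sub-pixel). Tie-breaks are deterministic and
conservative: equal sclera maxima resolve to the smallest depth; equal IRL
peak amplitudes resolve to the candidate closest to the ORL (smallest
thickness). Boundary depths are reported as pixel-center positions,
index × axial spacing.

Per-A-scan failures never abort a B-scan. Each A-scan carries a reason:
`no_valley` (no slope minimum above the sclera — this includes structure-free
columns whose smoothed maximum sits at depth index 0), `out_of_frame` (the
IRL exclusion zone extends entirely above the frame), or `no_peak` (no
admissible slope maximum).

Because every stage (Gaussian smoothing, differentiation, argmax, strict
extremum comparisons) commutes with positive affine maps of intensity,
segmentation output is exactly invariant under I → aI + b, a > 0. Loading
therefore only needs intensities on a consistent linear scale.

## Aggregation

For B-scan i, mean mᵢ and sample SD sᵢ (ddof = 1) are computed over its
valid A-scan thicknesses; its percentage error is 100·sᵢ/mᵢ (the
within-scan coefficient of variation — the only within-scan error measure
available at that stage). B-scans with percentage error strictly greater
than 25% are discarded, as are B-scans with fewer than `min_valid_fraction`
(default 0.5, a package choice) of their A-scans valid, or with no valid
A-scans. The volume estimate is

  RT = Σ (mᵢ/sᵢ) / Σ (1/sᵢ)   over retained B-scans,

with standard error equal to the unweighted sample SD of the retained means
divided by √n (None when fewer than two are retained). A retained B-scan
with sᵢ = 0 would carry infinite weight; it instead receives the largest
finite retained weight × 10 (configurable), preserving "most precise
dominates" while keeping the estimate finite; if every retained SD is zero
the weights are equal. Weighting by the B-scan SEM (sᵢ/√nᵢ) instead of the
SD is available via `weight_by_sem`.

Group comparison is a standard one-way ANOVA (scipy) with Bonferroni
post hoc: pooled-variance pairwise t-tests with p multiplied by the number
of pairs, capped at 1, at α = 0.05. If the data are totally degenerate
(all values identical, F undefined 0/0) the result is reported as
F = 0, p = 1.

## Phantom generator

An A-scan is modelled as

  I(z) = v + (r − v)·σ((z − z_IRL)/s) + (c − r)·σ((z − z_ORL)/s)
         + (S − c)·exp(−(z − z_sclera)²/2σ_b²)

with σ(·) the logistic function. Defaults: vitreous v = 4, retina r = 60,
choroid c = 25, sclera S = 150 (arbitrary linear units, sclera strictly
brightest), transition scale s = 5 μm, scleral band σ_b = 12 μm centered
50 μm below the ORL. The IRL surface is a low-order polynomial of
normalized lateral position and B-scan index (default: base 750 μm, gentle
5 μm B-scan tilt and 15 μm lateral curvature); the ORL is the IRL plus a
thickness surface (default flat 220 μm), which keeps thickness positive by
construction. Geometry defaults emulate a Spectralis-style rodent volume:
7 B-scans 240 μm apart, 768 A-scans, 496 depth pixels at 3.87 μm/px
(≈1.9 mm window; the depth pitch is a plausible configurable choice, since
scanner exports must always carry their own spacing metadata). The
thickness and layer defaults sit mid-range of healthy young rat retinas
(150–300 μm is the supported regime); the angular field of view enters only
through A-scan/B-scan counts and spacings — there is no optical distortion
model.

Ground truth is defined at the logistic transition midpoints, which
coincide with the slope extrema the detector targets, so "within one axial
pixel" statements are well defined. Optional distractors add a narrow
logistic edge at a chosen offset above the ORL with a chosen slope-peak
amplitude, to probe the 120 μm exclusion zone (an edge placed above the
zone with amplitude exceeding the IRL's captures the boundary — the
documented failure mode of the rule).

**Noise.** Each acquired frame carries fully developed multiplicative
speckle, modelled as unit-mean gamma noise with shape k per pixel, and the
stored B-scan is the mean of `art_frames` such frames (ART real-time
averaging, default 100). Since the mean of N unit-mean gamma(k) variables
is exactly gamma(N·k) with unit mean, the stored image is produced with a
single gamma draw of shape k·N; optional additive Gaussian read noise
follows, and intensities are clipped at zero. Defaults k = 50, N = 100
give a stored-image contrast of 1/√5000 ≈ 1.4%, which reproduces the
smooth slope profiles of averaged acquisitions. The model is pixel-iid
given the structure: it has no speckle grain correlation, no depth-dependent
attenuation or shadowing, no motion between averaged frames, and no optics.
Passing recovery tests on these phantoms therefore demonstrates the
geometric and statistical correctness of the pipeline, not robustness to
every artifact of in vivo imaging; heavily degraded real scans are expected
to be caught by the percentage-error discard rule rather than segmented
correctly.

## Numerical choices and degenerate inputs

- Physical-to-pixel conversion happens per volume from spacing metadata;
  all defaults (σ = 20, 2 μm; 120 μm; 25%) are in physical units.
- Reflective boundary handling for all smoothing; derivative is one-sided
  at the first/last depth sample.
- A constant B-scan yields all-invalid A-scans (`no_valley`), an
  unsummarizable B-scan, and a volume result of None with an explicit
  reason rather than an exception; the CLI records such volumes as
  `no_estimate` without failing the batch.
- Tabular output uses fixed 4-decimal formatting so written CSVs round-trip
  bit-identically as text.
- Phantom validation enforces the operating regime up front (IRL + 120 μm
  < ORL < scleral center, sclera brightest, all depths inside the frame,
  distractor edges inside the retina).

## Testing scale

Unit and property tests run on laterally reduced phantoms (16–64 A-scans,
2–3 B-scans) since every stage is per-A-scan; full 7 × 768 default volumes
are used for the geometry, recovery and bias checks. The speckle-bias check
averages 100 seeded default volumes. The whole suite runs in roughly two
minutes on one CPU.

## Known limitations

- Only the two retinal boundaries are segmented; choroidal interfaces and
  intra-retinal sublayers are out of scope.
- The first-valley ORL rule assumes a clean slope descent between the
  scleral shoulder and the choroid; at stored-image speckle contrasts well
  above what frame averaging leaves (≳5%), spurious slope minima near the
  scleral band systematically bias the ORL and the discard rule becomes the
  only safeguard.
- A distractor edge above the exclusion zone and stronger than the IRL
  transition captures the boundary by construction of the published rule.
- No eye-tracking, registration across timepoints, or proprietary scanner
  format parsing (export to image stacks first).
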