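# octrt

Automated retinal thickness quantification for rodent spectral-domain OCT
(SD-OCT) volume scans, plus a synthetic phantom generator with exact ground
truth so the whole pipeline can be validated without animal imaging.

It is aimed at vision researchers running longitudinal rodent studies (for
example oxygen-induced retinopathy models) who need an objective,
operator-free measurement of total retinal thickness from Spectralis-style
volume scans exported as image stacks.

## The algorithm

Each A-scan (depth profile) of every B-scan is segmented independently:

1. **Sclera anchor.** The B-scan is smoothed with a Gaussian filter of
   physical scale σ = 20 μm. The sclera is the brightest structure in a
   rodent B-scan, so the absolute intensity maximum of each smoothed A-scan
   marks the scleral center.
2. **Outer retinal boundary (ORL).** The axial intensity slope dI/dz is
   computed per A-scan after Gaussian smoothing with σ = 2 μm. Scanning
   upward (toward the vitreous) from the scleral center, the first valley of
   the slope marks the ORL.
3. **Inner retinal boundary (IRL).** The IRL is the highest slope peak more
   than 120 μm above the ORL; the exclusion zone prevents intra-retinal
   edges from capturing the boundary.
4. **Aggregation.** Per-A-scan retinal thickness is RT = z(ORL) − z(IRL).
   For each B-scan the mean and sample SD over its A-scans give a percentage
   error 100·SD/mean; B-scans with percentage error above 25% are discarded.
   The volume thickness is the average of the retained B-scan means weighted
   by 1/SD, and its uncertainty is the standard error among the retained
   B-scan means.

All scales are specified in micrometres and converted to pixels through
per-volume spacing metadata, so the method is resolution independent.
Group comparisons (one-way ANOVA, α = 0.05, Bonferroni post hoc) are
included as a thin reporting stage.

## Worked example

```python
from octrt import (PhantomSpec, SegmentationParams, generate_volume,
                   segment_volume, quantify_traces)

spec = PhantomSpec(seed=1)              # 7 B-scans x 768 A-scans, 240 um apart,
volume, truth = generate_volume(spec)   # speckle of an ART-100 acquisition
params = SegmentationParams()           # sigma 20/2 um, 120 um offset, 25 %

traces = segment_volume(volume, params)
summaries, result = quantify_traces(traces, params)
for s in summaries:
    print(f"B-scan {s.index}: mean {s.mean:.2f} um, sd {s.sd:.2f}, "
          f"pct_error {s.pct_error:.2f}%, retained {s.retained}")
print(f"volume thickness: {result.weighted_mean:.2f} +/- {result.se:.2f} um "
      f"({result.n_retained}/7 B-scans retained)")
print(f"ground truth:     {truth.thickness_um.mean():.2f} um")
```

prints

```
B-scan 0: mean 219.65 um, sd 2.17, pct_error 0.99%, retained True
B-scan 1: mean 219.84 um, sd 1.86, pct_error 0.85%, retained True
B-scan 2: mean 219.76 um, sd 2.13, pct_error 0.97%, retained True
B-scan 3: mean 219.81 um, sd 2.05, pct_error 0.93%, retained True
B-scan 4: mean 219.77 um, sd 2.02, pct_error 0.92%, retained True
B-scan 5: mean 219.70 um, sd 2.07, pct_error 0.94%, retained True
B-scan 6: mean 220.03 um, sd 2.01, pct_error 0.92%, retained True
volume thickness: 219.80 +/- 0.05 um (7/7 B-scans retained)
ground truth:     220.00 um
```

The phantom's true thickness is 220 μm; every B-scan has a sub-1% internal
coefficient of variation, so all 7 are retained, and the weighted volume
mean recovers the truth to 0.2 μm (well under the 3.87 μm axial pixel).

The same pipeline runs from the shell:

```
octrt simulate --outdir sim --seed 1
octrt segment --input sim/volume.tif --outdir seg
octrt compare --table cohort.csv --outdir stats
```

`segment` accepts real volumes as multi-page TIFFs or directories of
grayscale frames, with a JSON sidecar giving `axial_um_per_px`,
`lateral_um_per_px` and `bscan_spacing_um`. It writes per-A-scan boundary
tables, per-B-scan summaries, a volume summary JSON, and overlay PNGs of the
detected IRL/ORL/sclera curves.

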