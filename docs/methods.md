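# Methods

This note records the measurement model, the choices made where the
procedure admitted more than one reasonable reading, and what the synthetic
validation does and does not establish.

## Enrichment model

The per-sample statistic is built on sum-intensity projections because the
biological question is about total accumulated signal at the posterior, not
its z-distribution. Standardizing masked pixels with the *population* SD
(denominator *n*) treats the mask as the complete population of pixels for
that sample; across-sample statistics (the expression-filter threshold) use
the *sample* SD (denominator *n* − 1) because control embryos are a sample
from a population of embryos. The filter comparison is strict (>): a sample
exactly at the threshold is excluded.

The anteroposterior coordinate is normalized by the **mask's x bounding
box**, not the image width, so embryos that do not span the frame are
handled. Binning uses 100 equal-width bins; empty bins are filled by linear
interpolation between the nearest nonempty neighbours (edge bins take the
nearest value, which is what clamped linear interpolation produces). The
integrated posterior statistic is the **sum of bin means** whose centers lie
in the posterior 15%; summing bin means rather than raw pixel values makes
the statistic independent of pixel density per bin. Both the bin count and
the integration rule are exposed in `RunConfig` and recorded in output
headers, since other operationalizations of "interpolate … integrate" exist.

A consequence of projecting a 3D embryo worth stating: the projection of a
uniformly bright ellipsoid is thickness-weighted (dome-shaped), so posterior
z-scores of an *unenriched* embryo are negative, not zero. Enrichment
statistics are therefore comparative — they order samples and groups
correctly (validated by the amplitude-recovery test) — and should not be read
as absolute concentrations.

## Colocalization

The gate needs a mean and SD for the HA channel; these are computed over
**all masked pixels** of the projection, so the gate selects globally
HA-high pixels restricted to the posterior cap. Correlation uses raw
projected intensities; Pearson *r* is invariant under per-channel positive
affine maps, so gating on z-scored rather than raw intensities would select
the identical pixel set and give the identical *r* — the ambiguity is
documented rather than resolved. Fewer than 10 gated pixels is a hard error;
*r* on tiny pixel sets is unstable and no minimum is inherited from prior
practice.

## Radial profiling

The stack is linearly interpolated along z until the z-step matches the xy
pixel size (`new_nz = round((nz−1)·dz/dxy) + 1`, never below the original;
endpoints preserved), then cropped to the 3D mask bounding box and averaged
along the AP (x) axis into a yz cross-sectional image.

Two choices here deviate from the most literal reading of the workflow and
are deliberate:

* **Masked mean projection.** The x-average at each (z, y) position runs
  over in-mask voxels only. A plain average over the crop dims every pixel
  near the cross-section edge by the fraction of out-of-mask (zero) voxels
  along x — a pure curvature artifact that biases erosion profiles toward
  positive slopes and can swamp genuine cortical signal. With the masked
  mean, a uniformly bright embryo yields a flat profile (slope 0), which is
  the behaviour a radial statistic should have.
* **Otsu over the cropped field.** The Otsu histogram is taken over the
  whole cropped yz image, separating embryo cross-section from background;
  the initial erosion region is the Otsu-positive set intersected with the
  mask footprint. Restricting the histogram to the footprint instead splits
  rim from interior and, for cortical phenotypes, leaves a ring ~2–3 px wide
  that vanishes after two erosions — incompatible with a 20-iteration
  profile. An `erode_mask_instead` option erodes the whole footprint.

Erosion uses a 3×3 cross (4-connectivity) structuring element, the common
default; 8-connectivity is available and the choice is recorded in outputs.
Profiles are normalized by the iteration-0 mean so every profile starts at 1
and slopes are comparable across samples; the line is an ordinary
least-squares fit of normalized mean against iteration index. If the region
empties early the fit uses the available points, with a minimum of 5; below
that the sample errors out rather than returning a meaningless slope. Regions
are nested by construction (each step erodes the previous region), asserted
in tests. The slope is exactly invariant to positive scaling of the image
(normalization cancels it).

Otsu's threshold itself maximizes between-class variance over a 256-bin
histogram. Cuts through empty-bin gaps produce exactly tied objectives, and
the two algebraically equivalent forms of the objective round differently at
the 1e−16 level; ties are therefore detected with a 1e−12 relative tolerance
and broken toward the lower threshold, which makes the result stable and
reproducible against an exhaustive-search oracle.

## Inference

The bootstrap pools both groups and resamples with replacement at the
original group sizes — a bootstrap null of "no group difference" — and
reports the two-sided, +1-corrected p-value
(1 + #{|d_b| ≥ |d_obs|})/(B + 1), with B = 100,000 by default. The +1
correction keeps p ≥ 1/(B+1): Monte-Carlo p-values of exactly zero overstate
evidence. Resampling with versus without replacement, and sidedness, are
conventions; this one is stated in every output row rather than asserted as
the only possibility. No multiple-testing correction is applied by default
(raw per-comparison p-values at α = 0.05, matching how such panels are
conventionally reported); a Benjamini–Hochberg pass can be added downstream.
Per-comparison seeds are derived from the master seed via `SeedSequence`, so
adding a group does not perturb other rows.

JSD uses base-2 logarithms with 0·log 0 := 0, which makes the [0, 1] range
exact: 0 iff proportions are identical, 1 iff supports are disjoint. Counts
are converted to proportions first, so scaling a table by any positive
integer leaves the score unchanged.

## Synthetic-data generator

The generator emulates the acquisition regime the measurements were designed
for: by default a 30-slice stack at 2 µm z-step with 0.65 µm xy pixels
(a 60 µm stack at 20× magnification), an axis-aligned ellipsoidal embryo
inscribed in the volume with the AP axis along x and posterior at max x, and
these signal components:

* a uniform cytoplasmic base intensity (default 100 a.u.);
* a posterior cap, Gaussian in the normalized AP coordinate,
  A·exp(−(1−u)²/2s²) with width s = 0.1 of embryo length — smooth and
  monotone in A, which is all the enrichment statistic requires;
* granule puncta as isotropic Gaussian blobs (σ = 1.5 voxels, amplitude 80);
  with cortical fraction c, round(c·n) centers are drawn from the cortical
  shell (Euclidean distance to the mask boundary ≤ 3 voxels) and the rest
  from the strict interior (distance > shell depth). Placing the remainder
  strictly interior, rather than uniformly, makes c = 0 a genuinely interior
  phenotype so the two extremes form a proper two-class validation for the
  radial slope sign;
* paired channels sharing round(φ·n) granule centers (a seeded permutation
  picks the shared subset so it is unbiased with respect to placement);
* additive Gaussian noise (default SD 5 a.u., 5% of base) and optional
  Poisson shot noise (off by default so analytic examples stay exact).

All randomness flows through one `numpy` generator seeded per call; output
is a pure function of (parameters, seed).

What the generator does **not** emulate: optical PSF blurring and
anisotropic resolution, camera gain and offset, autofluorescence gradients,
embryo-to-embryo shape variation, imperfect masks, or multi-embryo fields.
Passing the recovery tests therefore shows the measurement chain is
correct and well-calibrated on images whose ground truth is known — it does
not certify segmentation quality or robustness to optical artifacts on real
micrographs, where mask quality is the dominant risk and is deliberately
left to external providers.

## Validation problem sizes

The recovery tests run on deliberately small volumes — (12, 48, 96) voxels
for enrichment and colocalization, (16, 40, 80) with a 2:1 z-anisotropy for
the radial workflow — chosen so the full suite exercises every stage,
including 100-embryo amplitude grids and 50-per-class slope classification,
in seconds. The statistics scale with pixel counts, not volume size, and the
same code paths run unchanged on full-resolution stacks.

## Degenerate inputs and numerical conventions

Constant masked regions raise zero-variance errors (z-score, Otsu, gate);
empty gates raise an error carrying the selection counts; groups below two
samples, fewer than two controls, or fewer than five erosion points raise
insufficient-data errors rather than producing silent NaNs. Floating-point
excursions of the JSD outside [0, 1] (order 1e−16) are clamped. Output CSVs
embed the package version and a SHA-256 digest of the configuration so any
result file can be traced to the exact constants that produced it.
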