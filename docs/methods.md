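# Methods

This note documents the models, parameter choices, numerical details and
limitations of `lipidstack`, in the order data flows through the package.

## Coordinate and unit conventions

Voxel grids are indexed `(z, y, x)`; physical spacing `(dz, dy, dx)` is in
micrometres and anisotropy is first-class (confocal stacks are typically
sampled at `dz = 10 µm` with `dx = dy ≈ 1 µm`). The physical coordinate of a
voxel is its centre, `((i + 0.5)·step)` per axis. All distances, areas and
volumes are computed in micrometres, never in voxel units, so results are
independent of the sampling grid. Droplet tables export physical coordinates
at 3-decimal precision and round-trip losslessly at that precision.

Stack spacing is read from TIFF/ImageJ/resolution metadata; any component the
file lacks must be supplied explicitly. There is deliberately no default
pixel size — a silent default would contaminate every downstream volume.

## Per-slice segmentation

**Intermodes thresholding.** The slice histogram is reduced to 256 bins
(8-bit images use the native grey levels; 16-bit images are rescaled so 256
bins span the slice's min–max range, and the returned threshold is mapped
back to native intensity). The histogram is smoothed with a 3-point moving
mean (zeros outside the bin range) until exactly two local maxima remain;
the threshold is the floor of the peak-midpoint. Two numerical details
matter:

* *Plateau handling.* Smoothing an exact delta mode produces a run of equal
  bins. A strict single-bin maximum test transiently drops such a mode from
  the count and can terminate at a spurious "bimodal" state between two
  foreground sub-peaks (we observed a threshold of 208 landing inside the
  droplet-intensity cluster on a noiseless image, losing every dimmer
  droplet). We therefore count an equal-valued plateau as one maximum at its
  centre.
* *Summation order.* Smoothing uses explicit `left + centre + right`
  accumulation so thousands of passes remain bit-reproducible against a
  scalar reference implementation.

Slices whose histogram cannot be reduced to two modes within the iteration
cap (default 10 000) — blank slices above and below the muscle — yield no
ROIs rather than failing the run. Per-slice thresholds are logged.

**Cleanup and splitting.** Foreground is `intensity > threshold`; holes are
filled; 8-connected components with area below `min_droplet_area`
(default 20 µm², a disk of radius ≈ 2.5 µm, below any adipocyte droplet) are
removed. Touching droplets are split by watershed on the negated
Gaussian-smoothed (σ = 1 px) Euclidean distance transform, with markers at
its local maxima (minimum separation 3 px); any component left without a
marker falls back to a single marker at its distance maximum, so foreground
is never lost. Particle registration uses second-moment ellipse fitting;
area is exactly `pixel_count · dy · dx`. The whole stage is deterministic.

## Cross-slice deduplication and volumes

Two ROIs at most `max_slice_gap` (default 1) slices apart belong to the same
droplet when their XY centroid distance is below
`max_centroid_gap · max(r_eq,1, r_eq,2)` with `r_eq = sqrt(area/π)` and
`max_centroid_gap = 1` by default: successive cross-sections of a sphere are
concentric, so centroid containment is the minimal correct criterion.
Matching is greedy per slice, ranked by centroid distance, then smaller area
difference, then lower x, then lower y; with hundreds of droplets per muscle
and near-spherical shapes a global assignment would change nothing while
costing quadratic time.

Each chain collapses to the member with the **maximal integrated intensity**
(mean intensity × pixel count), ties to the larger area, then the lower
slice. Integrated rather than mean intensity is essential: axial bleed can
leave a tiny out-of-focus cap whose few bright pixels out-average the true
in-focus cross-section, which would collapse a real droplet onto a
near-zero-area fragment. The droplet's XY centroid is the representative's
centroid; its Z is that slice's centre; its volume comes from that single
ROI — a near-circular ROI (aspect ≤ `sphere_aspect_cutoff = 1.1`) becomes a
sphere of the area-equivalent radius (so a circle's volume is exactly
reproducible from its area), an elongated one an ellipsoid with the in-plane
semi-minor axis reused as the Z semi-axis. Only the representative ROI's
volume ever enters results.

Manual ROIs enter as CSV (slice, pixel centre, semi-axes in µm) and are
converted with the same volume rule using `area = π·a·b`; a manual droplet
falling within the chaining criterion of an automatic droplet in the same or
an adjacent slice is rejected as a duplicate with a warning.

**Accuracy budget.** The representative cross-section sits up to `dz/2` from
the droplet's equator, giving a worst-case volume ratio
`(1 − (dz/2r)²)^{3/2}` — 0.65 for `r = 10 µm` at `dz = 10 µm`, 0.98 for
`r = 40 µm`. Per-droplet errors within 15% are therefore only guaranteed by
geometry for `r ≳ 16 µm`; totals, which large droplets dominate, are
typically within a few percent (see the validation below).

## Spatial metrics

The nearest-neighbor index is `mean observed NN distance / mean NN distance
under complete spatial randomness`, all distances 3D Euclidean in µm. The
CSR expectation is Monte Carlo-estimated (default 999 realizations, seed
recorded in provenance) by drawing the same number of points uniformly in a
chosen bounded domain — bounding box (default, of the points or explicit),
convex hull of the points, or a binary muscle mask — because muscle volumes
are bounded and anisotropic, so the unbounded-Poisson closed form
`0.554·λ^{−1/3}` is biased by edge effects; that closed form is reported
alongside for reference. An axis of zero extent is allowed when every point
shares that coordinate; distances then fall back to the remaining
dimensions (with the 2D constant `0.5·λ^{−1/2}` for the reference value).
Note that decellularization contracts the extracellular matrix, so absolute
inter-droplet distances in real muscles are relative, not anatomical; the
index, being a ratio, is less affected.

Serial-section adipocyte volumes use slab summation
`Σ area_i × section_thickness`; an alternative estimator (sphere from the
largest section, mirroring the confocal conversion) is available behind a
flag since the histology protocol does not fix the choice. Volume-histogram
comparisons report shared-bin counts and the two-sample KS statistic,
descriptively (no p-value).

## Calibration statistics

OD–volume calibration is ordinary least squares of optical density on
volume (matching the orientation in which such calibrations are plotted),
with duplicate well readings averaged per sample first and volume predicted
from a new OD by analytic inversion of the line. The relationship is
proportional but not 1:1, so absolute volumes from OD are only meaningful
through this calibration.

Measurement agreement uses ICC(2,1) — two-way random effects, absolute
agreement, single measure — computed from the mean-squares decomposition.
The absolute-agreement form is the right one for interchangeability claims
(it penalizes a constant offset between procedures); the consistency form
ICC(3,1) is available behind a flag. Degenerate inputs (fewer than 3
samples, zero total variance, all volumes equal) raise errors rather than
returning conventional values.

## Synthetic stacks

The generator emulates what the pipeline will see in decellularized-muscle
imaging: quasi-spherical bright droplets (lognormal radii, median 15 µm,
log-sd 0.4, clipped to [5, 50] µm; in-plane aspect uniform in [1.0, 1.3]) on
a dark background (droplet intensity 200 ± 20, background 10 on the 8-bit
scale), sampled at `(dz, dy, dx) = (10, 1, 1) µm`, default domain
400 × 400 × 200 µm. Droplets are placed uniformly or by a Thomas cluster
process, non-overlapping by rejection sampling (an overlap-allowed mode
exists for stress tests); out-of-plane fluorescence is modelled as an
axial-only Gaussian bleed (σ = 8 µm) — the artifact the Intermodes choice
targets — and noise is Gaussian (σ = 5 default) or Poisson. Ground truth
records every droplet's centre, semi-axes, exact analytic volume, and the
analytic elliptical cross-section in every intersected slice. A fixed seed
yields byte-identical stacks.

What the generator does **not** emulate: lateral PSF blur, ECM
autofluorescence texture, depth-dependent attenuation, droplet coalescence
or fractionation. Passing tests on synthetic stacks therefore validate the
geometry, bookkeeping and statistics of the pipeline, not its robustness to
every optical artifact of real confocal data.

## Validation at desk scale

The package's agreement claim is checked end to end: 12 synthetic stacks
(10–60 droplets, default bleed, Gaussian noise σ = 5) are measured by the
full pipeline and compared with ground-truth totals; ICC(2,1) across the
panel is ≈ 0.99 (threshold 0.95). Problem sizes throughout the test suite —
400 × 400 px slices, 20 slices, panels of 12–20 stacks, 100-seed trials for
directional claims, 999 Monte Carlo replicates for the CSR null — were
chosen so the whole suite runs in a few minutes on one core while keeping
Monte Carlo standard errors well inside the asserted tolerances.

## Known limitations

* Droplets smaller than ~1.5 × `dz` can be missed entirely (no slice centre
  falls inside) or measured far off the equator; their contribution to
  totals is small but counts are less reliable at the small end.
* With noise and bleed, the out-of-focus halo under a large droplet can
  fragment into small above-threshold ROIs that fail the centroid
  containment test and register as spurious tiny droplets (~0.2% of total
  volume in our panels). Raising `min_droplet_area` suppresses them.
* Two droplets nearly concentric in XY in adjacent slices can merge into one
  chain; non-overlap makes this rare, and it mirrors the single-ROI
  reduction's intrinsic ambiguity.
* Per-slice thresholds assume each slice containing droplets has a bimodal
  histogram; extremely sparse slices (one dim droplet) can fail the
  bimodality test and lose that slice's sections.
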