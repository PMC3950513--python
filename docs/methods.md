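# Methods

## The measurement

The package quantifies whether a "target" fluorescence channel
preferentially localizes at the foci of a "reference" channel inside
individual rod-shaped bacterial cells. Because a bacterium is only a
few hundred pixels of image, two unrelated signals will frequently sit
within a few hundred nanometres of each other by chance; the analysis
therefore never reports a raw overlap but always a distance
distribution against a matched in-cell random-placement control.

Per cell, the target is reduced to one point and the reference to zero
or more points, and the cell contributes the distance to the *nearest*
reference point. Distances from all cells form a cumulative
distribution `F(d)` with denominator equal to the total number of
cells; a cell with no reference focus can never colocalize, so `F`
plateaus at the fraction of cells that have at least one focus (the
asymptote) rather than at 1. The colocalization fraction is `F` at a
distance threshold:

* snapshot rule: within 4 px inclusive (516 nm at 129 nm/px);
* time-lapse rule: strictly less than 2 px (258 nm).

Both comparators are honoured verbatim and configurable. The fraction
carries a 95% Wilson score interval (Clopper–Pearson by flag).
Measured and random fractions are compared with a pooled two-proportion
z-test; the significance flag additionally requires the two 95%
intervals to be disjoint, the stricter criterion one applies when
reading error bars, so a flag is never raised on a p-value alone.

### Two localization modes

Channels that assemble diffraction-limited foci are localized by
candidate detection followed by least-squares fitting of
`offset + A * exp(-0.5 q^T Sigma^-1 q)` with a full elliptical
covariance, initialized from intensity moments of a 7×7 window. A fit
is accepted when it converges with the centroid inside the window,
positive amplitude, and both sigmas in [0.5, window/2] px; failures are
retained with a flag for auditability but excluded from statistics.
Channels with substantial diffuse signal are instead summarized by the
single brightest in-cell pixel (deterministic row-major tie-break),
which marks the subcellular site of highest residence time. This
distinction matters: a Gaussian fit to a diffuse channel would
hallucinate a centroid where there is no focus, while the brightest
pixel is always defined and always unique.

Candidate detection thresholds at in-cell mean + k·sd (k = 3 by
default) computed on a *sigma-clipped* background population, seeded
from median + k·1.4826·MAD and refined monotonically downward. The
clipping is essential: computed naively over all cell pixels, the
statistic is inflated by the foci themselves, and in a small cell
carrying three foci the naive threshold exceeds the focus peaks and
detection returns nothing. Candidates are the local intensity maxima
within the 8-connected supra-threshold region (one max per connected
cluster would merge two resolvable foci whose threshold skirts touch);
maxima closer than 2 px are merged, since emitters below that distance
are not separable at this PSF. During fitting, window pixels lying
closer to another candidate are excluded from the residuals, so a
neighbouring focus cannot drag the fit.

### Null models

Two controls mirror the two measurement directions. The random-pixel
null draws uniform pixels from the cell's mesh and measures them
against the real reference foci (the control when the target is a
brightest pixel). The random-focus-set null replaces each cell's
reference foci by an equal number of uniform in-cell points and
measures the real target against them (appropriate when the reference
channel has several foci per cell). The classic procedure draws one
random point per cell; the default here is 100 draws per cell averaged
within the cell before the curve, which reduces null variance without
changing its mean — `n_draws=1` reproduces the single-draw variant
exactly. On any mesh small enough to enumerate, the Monte-Carlo null
converges to the exact fraction of mesh pixels within threshold of the
nearest focus; this is asserted in the tests at 3 standard errors.

## The synthetic scene generator

Scenes emulate the imaging regime the analysis assumes: capsule-shaped
cells (rectangle with semicircular caps — the standard rod-cell
approximation) on a regular non-touching grid, rasterized by the
pixel-center rule at 129 nm/px. Defaults: 3.0 ± 0.4 µm length,
1.0 ± 0.05 µm width, reference focus count per cell drawn from
{1: 0.6, 2: 0.3, 3: 0.1}, PSF sigma 1.3 px, spot amplitude 500 and
background 50 photon counts with Poisson shot noise — chosen so
reference foci are bright and crisp while the target channel carries a
30% diffuse fraction spread over the cell, resembling a
condensin-interacting protein with a high cytoplasmic background. The
target point is tethered to a randomly chosen reference focus with
probability `coloc_prob` (isotropic Gaussian offset, default sd 1 px,
re-sampled up to 100 times if it lands outside the cell, then clipped
inward); otherwise it is uniform in the cell. Untethered placement and
the analysis-side random-pixel null are the same distribution by
construction, verified by a two-sample KS test in the suite.

Reference foci within one cell keep a minimum separation (default 6 px
≈ 0.8 µm, capped by what the cell's length can host, with an
evenly-spaced axial fallback for short crowded cells). This reflects
the biology being emulated — distinct condensin clusters occupy
separate chromosomal positions micrometres apart — and keeps the
recovery problem well-posed: foci placed closer than the diffraction
limit are one cluster optically, and no detector can count them as two.

Everything is driven by one seed; each cell consumes its own counter-
keyed RNG sub-stream and rendering uses a further stream, so scenes are
bit-reproducible and insensitive to evaluation order.

What the generator does *not* model: 3-D PSFs, camera gain/EM noise,
photobleaching, cell growth, bent or touching cells, chromatic offsets
between channels. Passing tests on these scenes therefore demonstrate
the statistics and the localization math, not robustness to crowded
fields or miscalibrated optics; real crowded fields should be segmented
externally and injected as label images.

## Parameter recovery and its honest target

With tethering probability p, the realized fraction of cells whose true
target lies within 4 px of a true focus is not p but roughly
`p + (1-p)·q`, where q ≈ 0.35 is the chance-coincidence level for these
cell geometries — randomly placed points in a ~3 × 1 µm cell are within
516 nm of a focus about a third of the time, which is exactly why the
random control exists. Recovery is therefore tested against the
scene's ground-truth realized fraction: across 20 replicate 500-cell
scenes per tethering level in {0, 0.25, 0.5, 0.75, 1}, the measured
fraction's 95% CI covers the ground truth in at least 90% of
replicates, and at p = 0 the significance flag fires in at most 10%.

## Line profiles, peaks, and time-lapse metrics

Line scans bin in-cell intensity by long-axis position (principal
component of the pixel coordinates; adequate for straight rods, a
documented limitation for bent cells) and are max-normalized to 100%.
A local maximum is a peak when it rises at least 5 percentage points
above its flanking points of inflection — implemented as the first bin
on each side where the discrete second difference turns positive, with
profile endpoints as fallback, and measured against the *higher* of the
two flanking values (the conservative reading). Profiles shorter than
5 bins carry too little curvature information and yield no peaks.

Track metrics operate on (time, axial position) series: the total
distance moved is the path length (sum of |Δposition| over consecutive
frames), not the net displacement, and a focus that splits contributes
its parent's path plus both daughters' paths. Frame linkage is greedy
nearest-neighbour with a 5 px maximum jump. Cohesion time is the delay
between the first frame with a replisome focus and the first frame with
two origin foci more than 2 px apart; on synthetic series with a
programmed lag it is recovered within one frame interval (the
irreducible sampling error of event timing).

## Numerical conventions

Coordinates are 0-based (row, col), pixel centers at integer positions;
all distances are computed in continuous pixel units and converted to
nm by multiplication with the pixel size (129 nm default, fixed by the
4 px = 516 nm pairing). Integer brightest-pixel positions are compared
with continuous centroids without half-pixel correction. Ties in the
brightest-pixel search break to the smallest (row, col) in row-major
order. Cells touching in the image are not split; the segmenter's
warranty covers non-touching fields. ABSENT distance records (cells
with no reference focus) keep their denominator role in every fraction
— the alternative cells-with-foci denominator is available but
non-default, since the all-cells form is what makes the asymptote
interpretable.

## Problem sizes

The test suite and the acceptance script use 500-cell scenes for
recovery statistics (CI half-width ≈ 0.03–0.04), 200-cell scenes for
false-positive control, 10⁴ draws for the null-vs-enumeration check,
and 200 repeats for the noisy-localization RMSE; these sizes give each
assertion a comfortable margin relative to its tolerance while keeping
a full run to a few minutes.
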