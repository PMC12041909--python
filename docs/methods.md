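# Methods

This note documents the models behind each analysis stage, the defaults
and why they were chosen, what the synthetic-data generators do and do
not emulate, and the numerical choices that matter.

## Synthetic data

All generators draw from a single `numpy.random.Generator` seeded
explicitly; identical parameters (including the seed) give bit-identical
output. Defaults follow the acquisition geometry of the experiments the
toolkit targets: 200-frame movies at 40 Hz for single-molecule imaging
and 0.5 μm z-steps for confinement stacks. The TIRF camera pixel size is
not a published constant of the setup; the default of 0.16 μm/px (a
typical EMCCD pixel behind a 100× objective) is configurable everywhere.

**Single-molecule movies.** The initial molecule count is Poisson with
mean density × field area; mobile molecules take 2D Gaussian steps of
per-axis variance 2·D/frame_rate with reflecting boundaries (which
preserve the density in the field of view); each molecule bleaches
irreversibly with a per-frame probability (geometric lifetime).
Per-molecule brightness is drawn once from a log-normal with configurable
mean and CV and stays constant until bleaching — the density estimator
divides by a *mean single-molecule brightness*, which presumes a stable
per-molecule value. Spots are rendered as *integrated* 2D Gaussians
(error-function pixel integrals, ±4σ window, < 10⁻³ relative truncation),
matching how spot size is later measured by the fitter. Not emulated:
blinking or multi-step photophysics, EM-gain noise statistics, 3D/astigmatic
PSFs, drift.

**Fura-2 stacks.** Cells are rendered as disks (area enters through the
radius) with a one-pixel anti-aliased rim; the 380 nm channel carries a
constant amplitude times coverage and the 340 nm channel carries
ratio × amplitude, so the background-corrected pixel ratio equals the
specified ratio curve exactly wherever the cell has coverage. Overlaps
between cells are detected, warned about and recorded in the truth
table. Real cells are amoeboid, show spatial calcium gradients and
photobleach; none of that is emulated, so passing recovery tests
demonstrates correctness of the measurement chain, not robustness to
every biological morphology.

**Confinement phantoms.** A confined, membrane-stained cell appears in z
as two bright lamellae (top and bottom plasma membrane) separated by the
confinement height, each Gaussian along z (default σ 0.4 μm, an
effective axial-response width), plus a dim lateral shell at the cell
rim. The z-range covers both lamellae with a margin of max(3σ, 1 μm).

**Immunostain phantoms** place non-overlapping nucleus-in-cell disk
pairs by rejection sampling (bounded retries, then an explicit placement
error). **Deflection profiles** are an even polynomial shape with unit
apex and vanishing rim (default parabola 1 − u²), scaled linearly with
pressure, plus optional Gaussian noise.

## Bilayer characterization

Localization detects maxima of a lightly smoothed frame above a count
threshold and refines each with a symmetric integrated-Gaussian fit
(Gauss-Newton with analytic Jacobians, batched over spots; parameters
x, y, σ, integrated brightness, local background). *Size* is the fitted
Gaussian σ in pixels: the size filter bounds (0.75, 1.25) px are of
order 1, consistent with σ rather than a FWHM or diameter. Duplicates
within 1 px are merged keeping the brighter; saturated spots (dtype
maximum, for integer data) are flagged, not fitted.

The single-molecule regime begins at the first frame whose size-filtered
localization density is ≤ 0.09 μm⁻² (the comparison is inclusive: a
frame exactly at threshold qualifies). The single-molecule brightness is
the mean integrated brightness over the following 10 frames. Density is
the background-corrected mean brightness per μm² of the *first* frame
divided by that single-molecule brightness; background defaults to the
median of a user-designated molecule-free ROI, falling back to the 1st
percentile of the first frame (the measurement itself does not pin this
down, so it is exposed in config).

Linking assigns localizations between consecutive frames by minimising
total squared displacement (Hungarian algorithm) among pairs within a
6 px search radius, with no gap closing. The diffusion constant comes
from a weighted linear fit MSD(t) = 4Dt + c over the first 5 lags of the
ensemble MSD of tracks with ≥ 5 steps, with weights ∝ number of
contributing pairs and c ≥ 0 absorbing localization error; the lag-0
point is never used, and the lag range is a documented choice (short
lags carry the least tracking ambiguity). The mobile fraction counts
tracks whose individual MSD slope exceeds D = 0.01 μm²/s; this cutoff is
a parameter because "mobile" has no unique criterion — for bilayer
ligands at ~1 μm²/s the result is insensitive to it over two orders of
magnitude.

## Fura-2 pipeline

Ratio stacks are (I340 − B340)/(I380 − B380) with pixels masked invalid
(NaN, never infinite) where the corrected denominator is ≤ 0;
backgrounds are per-recording constants (median of a cell-free ROI in
practice). Segmentation of the sum stack is Gaussian smoothing (σ 1 px)
→ global Otsu → hole filling → watershed on distance-transform maxima →
removal of objects under 20 μm²; every step's parameter is in config,
since the recipe itself is this package's choice of a standard pipeline.
A cell's Ca²⁺ ratio is the mean of per-pixel ratios over its segmented
footprint (not the ratio of channel means). Cells touching the image
border have censored areas and are flagged.

Tracking is greedy nearest-centroid with a 15 μm per-frame limit and no
gap closing. Pre- and post-confinement recordings of the same field are
joined by centroid proximity (25 μm limit, nearest pairs first, ties to
the lower cell id); unmatched cells are kept and flagged. Window
statistics compare per-cell means of area and ratio between two
non-overlapping frame windows; the window extents are mandatory inputs
because the unconfined→confined transition time varies per experiment.

## Motility model

All trajectories of a condition are pooled; MSD(ℓ) averages squared
displacements over all tracks and all (overlapping) start frames —
overlapping pairs are standard and lower-variance than independent
pairs. The model MSD = 4Dt + V²t² + 4PA² is linear in (D, V², PA²) ≥ 0,
so the weighted fit is solved exactly by non-negative least squares: no
initialisation, no convergence tolerance, and nested models (pure
diffusion, pure drift) are recovered exactly on noiseless curves. The
default fit range is ¼ of the median track length. Bootstrap SDs
resample whole trajectories (the natural exchangeable unit) with
replacement, implemented as multinomial weights over per-track lag sums
so a thousand replicates cost one matrix product plus small NNLS solves.

Per-cell kinematics: average local velocity is the frame-to-frame speed
smoothed by a sliding mean (default 3 frames), reported in μm/min;
directional persistence is net displacement over path length (1 =
straight, → 0 for closed paths, defined as 0 for zero path length).
These definitions are this package's explicit implementation of
windowed-speed/straightness descriptors; they are deliberately simple
and stated here rather than inherited from any specific prior code.

## Immunostain quantification

Both channels are segmented with the same recipe as the Fura-2 stage
(nuclei with a smaller minimum area). Mean pErk1/2 intensity is measured
within each pErk-segmented cell; nuclei pair with the cell containing
their centroid, and orphans are retained flagged `unpaired`. Single
2D planes are assumed (no projection, no flat-field correction; a
correction hook exists in config for real data).

## Mechanics

Cell height: the axial profile through the lateral intensity centroid
(3×3 average) is searched for local maxima; the two outermost peaks are
refined by 3-point parabolic interpolation — on log-intensity when the
three samples are positive, which is exact for Gaussian lamellae — and
their distance is the height, with uncertainty ≥ z_step/2. If the
lamellae merge, the envelope FWHM is reported instead (an upper bound);
an envelope narrower than 2 z-steps is an explicit "unresolvable" error.

Deflection profiles are fitted with even powers of x only (symmetry
about the apex), default order 12, in a rim-normalised coordinate for
conditioning; rank deficiency reduces the order with a warning. Arc
length uses adaptive quadrature at 10⁻⁹ relative tolerance and agrees
with the closed form for parabolas to < 10⁻⁸ over rim slopes up to 1.
Engineering strain is referenced to the flat chord 2a — the membrane is
flat before pressurisation — and is invariant to profile translation and
reflection. The pressure fit is ordinary least squares of apex height on
pressure; the gap resolution is slope × 0.1 mbar (the pressure
controller's step). Expected-gap maps level the topography so a
designated reference region has zero mean, then report min/mean/max gap
and coplanarity (max − min) within the disc footprint.

## Statistics

Welch's t statistic and Welch–Satterthwaite df are computed from the
closed forms (two zero-variance samples: p = 1 if means agree, else 0).
Games-Howell uses q = |mᵢ − mⱼ|/√((sᵢ²/nᵢ + sⱼ²/nⱼ)/2) with a Welch-type
per-pair df and p from the studentized-range distribution with k groups
(SciPy's implementation, accurate far beyond the 10⁻⁴ target); pairs of
zero-variance groups fall back to pooled df. Boxplot summaries use
type-7 (linear-interpolation) quartiles, notch half-width
1.57 × IQR/√n (McGill's ~95% median-comparison convention) and the
1.5×IQR outlier rule. The test suite cross-checks Welch p-values against
an independent reference implementation to 10⁻⁸, verifies the ~5% type-I
error rate under the null at n = 20 over 10⁴ simulations, and checks
Games-Howell against an independent package.

## Problem sizes and limitations

Validation simulations are sized for desk-scale runs: single-molecule
fields of 15–20 μm at up to 0.5 μm⁻², 150–200 frames; Fura-2 phantoms of
6 cells over 2 × 10 frames at 0.5 μm/px; motility experiments of
200–500 tracks × 100 steps; 50-repetition bootstrap coverage at 300
replicates. These sizes give estimator standard errors comfortably
inside the tolerances being checked while keeping the default test run
short.

Known limitations: the localization density bias grows near the
single-molecule threshold if spots overlap heavily (duplicate merging
keeps the brighter spot and slightly inflates its brightness); greedy
cell tracking can mislabel cells that approach within the displacement
limit in one frame; the FWHM height fallback overestimates merged-lamella
heights by the axial response width; and the boxplot-notch/Welch
agreement is a consistency expectation, not a theorem — it is logged by
a statistical test, not asserted as an invariant.
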