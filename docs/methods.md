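# Methods

This note documents the measurement procedures, the synthetic-data model that
verifies them, the numerical choices, and what passing tests do and do not
establish about real data.

## Measurement procedures

### Per-cell Pearson colocalization

The colocalization score of a tested reporter with the reference PM marker is
the plain Pearson correlation coefficient over *all* pixels of a cell mask.
No Costes/Otsu pre-thresholding is applied: whole-cell-mask PCC is the
documented choice, and whether an automatic threshold would change real-data
scores is recorded as a sensitivity question, not guessed. Cells touching the
image border are removed before measurement (`exclude_border_cells`, an
idempotent operation that preserves label ids). Cells with zero variance in
either channel have no defined PCC; they are flagged and excluded from
summaries rather than set to 0, which would bias medians.

Group comparisons follow a hierarchical ("superplot") design: cell-level
PCCs are averaged per independent experiment, normality of those experiment
means is checked with Shapiro–Wilk (which needs at least 3 experiments per
group — fewer is a hard error), and an unpaired two-sample *t* test is run on
the means. The default is Student's pooled-variance *t* (the generic
"unpaired t test"); Welch is available by flag. A Shapiro–Wilk p < 0.05 in
either group flags the comparison as normality-questionable; the flag is
reported, never auto-switched on. Summaries report median and interquartile
range using linear-interpolation (type-7) quantiles — stated explicitly
because plotting libraries disagree on the rule.

### PM/cytoplasm enrichment ratio

From each cell mask two ROIs are derived: the PM ring (cell minus its erosion
by `ring_width_px`) and the cytoplasm (erosion by `erosion_depth_px`). The
ring width (default 3 px) and erosion depth (default 6 px) are free
parameters — at 0.1 µm/px a 3 px ring spans the optical blur of the membrane.
Cells eroded away entirely are dropped with a logged reason. Fluorescent
background is removed by subtracting a median-filtered duplicate of the image
before measuring; the enrichment is the ratio of ROI means. The ratio is
invariant to multiplicative rescaling; a non-positive cytoplasmic mean makes
it undefined (flagged). Pre/post comparisons are made between frames acquired
at matched optical conditions.

The analysis kernel is quoted as 100 px in the field; an even kernel has no
center pixel, so the nearest odd value 101 is used, with reflective edge
handling. Negative residuals are clamped to 0 by default (configurable, since
the original macros do not state the behavior).

### Sorting coefficient

For one invagination per cell, four line profiles are taken (tested and
reference channel, across the invagination and across an adjacent
non-invaginated PM patch). Each profile is background-subtracted, clamped at
zero (densities are physical), then integrated; the sorting coefficient is
the ratio of tested/reference density ratios, invagination over plain PM.
Background subtraction strictly precedes integration — the operations do not
commute once clamping is involved, and a constructed counterexample test
pins the order. The default background is the mean of a user-supplied
cell-free ROI per channel; a per-profile-minimum rule is available. Whether a
"density" is a sum or mean over the profile is not standardized; the sum is
used, which cancels in the ratio when profile lengths match, and lengths are
recorded so the choice is auditable. Profiles with saturated pixels are
flagged. Line profiles are sampled by bilinear interpolation at `step_px`
intervals along a polyline and averaged across a perpendicular band of
`2·half_width + 1` lines (default half-width 1, i.e. a 3 px band; line width
is not standardized in the field).

### Invagination screen statistic

The reference-channel image is enhanced with a white top-hat (image minus its
morphological opening; "top-hat deconvolution" in vendor terminology is
interpreted as this standard filter). The structuring element is a disk of
radius 7 px by default — larger than an invagination's half-width, smaller
than a cell. Invaginations are segmented per cell *in the cell interior*
(the cell eroded by the ring width): invaginations are inward structures, and
without this restriction the equally thin, equally bright PM ring itself
would dominate the segmented area. The threshold is per-cell
`median + 5·MAD` of the enhanced interior, chosen for robustness and for
scale invariance (the whole pipeline is invariant to a global intensity
factor); an absolute threshold is available. Components under 4 px are
discarded as noise. The per-cell statistic is the invagination area sum
divided by the cell area; condition means are divided by the vehicle mean at
the same timepoint within the same experiment, so the vehicle condition is 1
by construction and the statistic is scale-free within an experiment.

### Droplet volumetry and kymographs

Lipid droplets are 3-D connected components above a threshold (default Otsu
on the stack; 26-connectivity, matching the common plugin default; both
configurable since neither is standardized — the unrecorded threshold is the
main source of non-reproducibility for absolute volumes). Volume is voxel
count × voxel volume with anisotropic voxels; objects smaller than 2 voxels
are discarded as shot noise; objects are assigned to cells by majority
overlap with a 2-D mask extruded along z or a 3-D label volume. Kymographs
stack the profile of one fixed line across the frames of a (stabilized)
timelapse; the default regime is 31 frames at 1-min intervals.

## Synthetic-data model

`synthgen` paints elliptical cells (default radii 20–25 px at 0.1 µm/px,
i.e. yeast of 4–5 µm imaged at high magnification) with a PM ring of width
3 px. The tested channel emits a photon budget `base_intensity × cell_area`
(default 200 photons/px equivalent — moderate-SNR live-cell imaging); a
fraction `pm_fraction` is spread uniformly over the membrane pixels and the
rest over the whole cell, giving per-pixel expectations

- cytoplasm `c = B(1 − p)`,
- plain ring `c + m` with `m = B·p·A_cell/A_membrane`,
- invagination `s · e · (c + m)`,
- focus `c + foci_intensity`,

where `s` is the cell's true sorting factor and `e` the reference reporter's
own invagination enrichment (default 3, emulating the accumulation of the
PI(4,5)P2 marker in invaginations). The reference channel paints `B` on the
ring, `e·B` in invaginations and a 0.2·B cytosolic floor. Consequences used
by the tests: the true PM/cytoplasm contrast is `1 + p/(1−p)·A_cell/A_mem`,
strictly increasing in `p`; the noise-free ratio-of-ratios equals `s`
exactly; and with `p = 0` the tested channel is uniform over the cell.

Invaginations are finger-shaped inward extensions of the ring (depth 8 px,
width 3 px by default) at RNG-drawn angles; their axes are recorded so
truth-guided line ROIs can be constructed (`truth_profile_lines` places a
profile along the finger axis, inset 1 px from the ends, and a matched
tangential profile at mid-ring depth on the far side of the cell). Foci are
2 px-radius disks placed in the interior without touching other regions. All
per-cell region masks (ring, invaginations, cytoplasm, foci) are pairwise
disjoint and contained in the cell mask.

Internalization kinetics after a treatment time t₀ follow

    p(t) = p_end + (p₀ + a·e^(−d(t−t₀)) − p_end) · e^(−k(t−t₀)),  t ≥ t₀

constant before t₀ and clipped to [0, 1]. The exponential spike-and-decay
form is a configurable invention: the emulated biology is only qualitative
(a small transient PM increase of the sterol reporter, then rapid
internalization), so the spike amplitude default is 0 and any chosen value
is arbitrary by construction. Signal leaving the membrane reappears in the
cell's foci (mass-conserving), emulating endosomal accumulation. The true
`p(t)` curve is stored per cell; a log-linear fit of the truth curve returns
`k` to machine precision, which pins the generator's functional form.

The camera model is `Poisson(photons)·gain + N(0, read_sigma) + background
plane` (defaults: gain 2 ADU/photon, read σ 2 ADU, background 100 ADU, flat).
One RNG stream (PCG64, recorded seed) drives each call, so identical seeds
give bit-identical stacks. With gain 1 and no read noise the per-pixel
variance equals the mean (verified over >10⁴ pixels). `NoiseSpec.noiseless()`
disables the stochastic terms entirely, making every region mean exactly its
analytic expectation.

Droplet stacks paint spheres (radius ≥ 1 voxel, default 0.25 µm at
0.2×0.1×0.1 µm voxels) at non-touching RNG positions; the truth volume of a
droplet is its painted voxel count times the voxel volume, so volumetry can
be checked voxel-exactly.

**What the generator does not emulate:** point-spread-function blur, optical
sectioning, photobleaching, cell growth and division, stage drift, and
segmentation errors of a learned segmenter (external masks are the primary
input path; the built-in threshold/watershed segmenter exists so tests need
no learned model). Passing tests therefore establish the correctness of the
measurement arithmetic and its statistical behavior under realistic
shot/read noise — not robustness to optical artifacts or mis-segmentation on
real images.

## Numerical choices

- Coordinates are 0-based `(row, col)`; all 2-D morphology uses
  8-connectivity and disk structuring elements.
- The built-in segmenter smooths (Gaussian σ 2 px), Otsu-thresholds, fills
  holes (equatorial-plane cells are rings), erodes by σ to undo the
  smoothing-induced dilation of the bright ring, and splits touching cells by
  distance-transform watershed.
- The large-kernel median background is evaluated on a decimated grid
  (stride `kernel//25`) and bilinearly upsampled; the background varies
  slowly at the kernel scale, and the dense filter is used automatically for
  kernels ≤ 31 px (and exactly matches a brute-force sliding median there).
- Degenerate inputs are flagged, not fudged: zero-variance cells (PCC),
  non-positive denominators (enrichment ratio, sorting coefficient), zero
  vehicle means, fully eroded cells. Flags propagate into the tidy CSV.
- The end-to-end driver derives all sub-seeds from one config seed; the
  provenance JSON (config + seed + versions) reproduces per-cell CSVs
  bit-exactly.

## Problem sizes

Verification runs use fields of 128–256 px with 1–6 cells, 6–10-frame
timelapses, and 20–30 seeds per recovery or direction-of-effect statistic;
these sizes give stable medians (parameter recovery within a few percent)
while keeping the full suite fast. Direction-of-effect conclusions use
one-sided paired Wilcoxon tests over seeds at α = 0.01.

## Known limitations

- Absolute invagination areas and droplet volumes depend on unrecorded
  thresholds in the original instruments' software; only the normalization
  chains and relative statements are reproducible, which is why acceptance is
  property-based on synthetic truth rather than figure-value matching.
- The sorting-coefficient pipeline assumes user-placed (here: truth-guided)
  line ROIs; automatic invagination-line placement is out of scope.
- Per-frame masks are matched by maximal overlap as a utility; there is no
  tracking across frames.
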