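# Methods

`dropletquant` counts and measures bright fluorescent puncta — lipid
droplets stained with BODIPY 493/503, or Repo-positive glial nuclei — in
confocal z-stacks of whole-mount *Drosophila* brains. The pipeline has four
stages: tissue delineation, per-slice iterative particle detection,
z-dimension doublet removal, and per-brain summarization. Every stage is
deterministic: identical input and configuration give bitwise-identical
output.

## Tissue (ROI) delineation

Whole-mount brains image as a single bright contiguous region on a dark
background, so the region of interest is recovered once per stack from the
maximum-intensity projection: Gaussian smoothing (`roi_sigma`, default 2 px),
a global threshold, binary closing (radius 5 px), hole filling, and keeping
the largest 8-connected component. The mask is shared across slices; the
anatomical region is stable over a typical 12-slice acquisition and a
per-slice mask would flicker.

The default threshold is the triangle method, which is robust for the
skewed, background-dominated histogram of a projection; Otsu and a fixed
cutoff are available. One robustification matters in practice: droplets are
sparse but can be an order of magnitude brighter than tissue, and they drag
a histogram-shape threshold above the tissue level, collapsing the mask onto
the brightest punctum. The threshold is therefore computed on the projection
with intensities capped at the 99.5th percentile (`clip_percentile`), then
applied to the uncapped image. With these defaults the mask of a synthetic
tissue disc recovers the planted area to within ~7% (the residual bias is
the smoothed boundary skirt the triangle threshold includes).

If delineation yields an empty mask the tool falls back to a full-frame
mask (with a warning and `origin = "full-frame"` in the provenance record),
unless the fallback is disabled, in which case it is an error. A
user-supplied mask bypasses delineation entirely. For sub-regions such as
the antennal lobe neuropil, supply a hand-drawn mask; the tool does not
segment anatomy.

## Iterative particle detection

Each slice is processed independently. Per iteration:

1. **Smooth** a working copy of the slice with a Gaussian (`sigma`,
   default 1 px, reflecting boundary). Smoothing stabilizes detection only;
   all intensity statistics are measured on the original, unblurred slice.
2. **Threshold** with the Kapur–Sahoo–Wong maximum-entropy criterion on the
   within-ROI histogram of the smoothed working copy: choose the gray level
   `t` maximizing `H_bg(t) + H_fg(t)`, where each class's probabilities are
   renormalized and `H = −Σ p ln p` (natural log; the base shifts both
   entropies by a constant factor and cannot change the argmax). Ties break
   toward the smallest `t`. Histograms use 256 bins spanning the observed
   within-ROI min–max of the smoothed image, for both 8- and 16-bit data.
   The histogram is restricted to the ROI so the dark exterior cannot
   dominate the background class. Each iteration's threshold (intensity
   units) is clamped to be no higher than the previous iteration's: later
   passes target dimmer particles by construction, and re-binning over the
   shrunken post-erase range can otherwise nudge the value up by about one
   intensity unit. Numerically, class masses use exact suffix sums — the
   complement `1 − cumsum` carries rounding residue that can make an empty
   foreground class look admissible.
3. **Extract and measure** the 8-connected components of the binary image.
   A component is kept iff it satisfies the ROI containment rule (default:
   its centroid lies inside the ROI; `full` requires every pixel inside),
   its area is within `[min_area, max_area]` (defaults 4 and 10,000 px), and
   its circularity `4πA/P²` is at least `min_circularity` (default 0 —
   circularity is reported, not filtered). The perimeter is scikit-image's
   weighted boundary estimator, under which a rasterized disc scores ≈ 1;
   a zero perimeter returns circularity 1 by convention.
4. **Erase** each kept particle from the working copy, overwriting exactly
   its pixels with the slice's within-ROI background median (or 0 with
   `erase_fill: zero`). Erasing the brightest particles reshapes the
   histogram, so the next pass settles on a lower threshold and surfaces
   dimmer particles.

The loop runs up to `max_iterations` times (default 3) and stops early when
a pass finds nothing, the histogram degenerates (fewer than two populated
bins — e.g. a constant slice), or the threshold reaches the noise floor
(below). All thresholds are logged per slice and iteration.

Two guards keep later, lower-threshold passes honest:

- **Erase margin** (`erase_margin`, default 4 px). Erasing a thresholded
  core leaves the particle's PSF skirt in place; once the threshold drops,
  that skirt re-surfaces as a spurious dim ring. Pixels within the margin of
  any erased particle are barred from re-detection (the erase itself still
  touches exactly the particle's pixels). Four pixels covers the skirt of a
  particle ~100× brighter than the read noise under a ~1 px PSF, where the
  blurred edge falls below noise about 3.2 PSF widths beyond the core.
  A side effect is that particle pixel sets are pairwise disjoint across
  iterations of a slice, which the tests assert.
- **Noise floor** (`noise_floor_k`, default 3.0). Once real particles are
  erased, the maximum-entropy criterion will happily split pure noise. The
  loop stops when the threshold falls to or below
  `median + k·(1.4826·MAD)` of the smoothed within-ROI signal.

## Doublet removal along z

A droplet a few micrometres across intersects several optical sections, so
the per-slice detector reports it repeatedly. Particles whose slice indices
differ by at most `max_z_gap` (default 1) and whose (y, x) centroid distance
is at most `link_radius` (default 5 px) are linked; connected components of
that graph (transitive chaining allowed) are treated as one physical object,
and only the largest member (greatest pixel area) is retained. Ties break
toward the lower slice, then lower y, then lower x. Matching is by centroid
distance rather than pixel overlap because consecutive cross-sections of one
droplet can differ markedly in size. A chain spanning three or more slices
still collapses to a single retained particle. Discarded doublets remain in
the output table flagged `kept_after_dedup = false` for audit; summaries use
retained particles only. Deduplication is idempotent.

## Summaries and group comparisons

Per brain: particle count, density (count per ROI area, in px⁻² and µm⁻²
when the pixel size is known), total and mean particle surface, and the
circularity mean and quartiles. "Surface" of a droplet population can mean
either the summed or the per-droplet mean cross-section, so both are
reported. Group results are expressed as fold changes over the control-group
mean, so control brains average to exactly 1 and the comparison is invariant
to overall intensity or magnification scale. No hypothesis testing happens
in the tool; the CSVs are designed to feed external statistics.

## Synthetic benchmark

The generator renders what the detector relies on and nothing more: a flat
tissue disc (intensity 30) over dark background (10) with Gaussian read
noise (sd = background/5 = 2), and quasi-spherical droplets placed uniformly
in the disc with non-overlapping rims. Each droplet spans 3–5 consecutive
slices with its cross-section radius shrinking away from the central slice
as for a sphere; each slice is blurred with a 1 px Gaussian PSF and
quantized to 8 bits. Droplet peak amplitudes are log-uniform between 3× and
20× background — log-uniform so that no single threshold catches nearly
everything and the iterative passes have work to do, which is the regime the
detector is designed for. The standard benchmark (`examples/benchmark.yaml`,
identical to `SyntheticSpec()` defaults) plants K = 60 droplets of radius
2–6 px over 12 slices of 512×512, seed 0.

Scoring is greedy nearest-centroid matching in the (y, x) plane against the
planted centers (tolerance 4 px), each detection and each truth record used
at most once. An empty detection set has precision 1 by convention — it
asserts nothing false. Recall is also reported per decile of planted peak
amplitude, which is what exposes the benefit of iteration: at the benchmark
seed, single-pass detection recovers 17% of the dimmest decile while three
passes recover all of it.

What the generator does **not** emulate: tissue texture and autofluorescence
gradients, droplet clustering and touching droplets, anisotropic or
depth-varying PSFs, bleaching across slices, and saturated pixels. Passing
the benchmark therefore shows the algorithm recovers known objects under
idealized noise, not that the default configuration is optimal for any
particular microscope; on real data the size bounds, blur, and link radius
should be reviewed against the pixel size.

## Numerical and degenerate-input conventions

- Coordinates are 0-based, (z, y, x), origin at the top-left of slice 0.
- A constant slice (or empty ROI) is particle-free, not an error.
- A single-slice stack is valid; doublet removal degenerates to same-slice
  linking only.
- Same-slice particles within `link_radius` are linked (|Δz| = 0 ≤
  `max_z_gap`): two detections that close are re-detections of one object.
- Particle tables are sorted by (slice, centroid_y, centroid_x) so repeated
  runs are byte-identical.
- Multichannel TIFFs are rejected unless a channel index is given; silent
  channel choice is a reproducibility hazard.

## Problem sizes

The shipped tests and the acceptance script run the full pipeline on the
12 × 512 × 512 benchmark (about a second per detect run), 1,000-histogram
threshold-oracle sweeps, and 100 random particle sets for the
deduplication oracle.
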