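# Methods

This note documents the models, conventions and numerical choices behind
`opticell`, what the synthetic data do and do not emulate, and the
limitations that follow.

## Coordinate and spectral conventions

* Stage frame in micrometres, x rightward, y downward, matching pixel axes;
  0-based pixel indices with the origin at the top-left pixel centre;
  `stage = offset + pixel · pixel_size`. Boundary polygons are simple,
  counter-clockwise (positive shoelace area) in this frame.
* Acquisition window m/z 700–1000, 0.05 s per scan. The analysis grid is
  3,000 half-open bins [700 + 0.1·i, 700 + 0.1·(i+1)), lower edge inclusive,
  floor indexing; m/z = 1000.0 falls outside. Binning sums intensities per
  bin and therefore conserves in-range total intensity exactly before
  normalization.
* Normalization is total-ion (the binned vector is divided by its grand
  total). It is the standard choice for spectral classification and makes
  downstream results invariant to overall capture efficiency; an all-zero
  spectrum is passed through unnormalized. Alternative normalizations can be
  applied upstream since `normalize_and_bin(..., normalize=False)` exposes
  the raw binned vector.

## Synthetic data: what is emulated

**Images.** Cells are absorbing bodies in bright-field microscopy, so they
are rendered as ellipses darker than a flat background (default background
3000, contrast 1800 counts on a 16-bit scale) with i.i.d. Gaussian pixel
noise. The algae scenes use ~4–6 µm semi-axes at 0.5 µm/px; onion-scale
scenes simply scale the ellipse axes up. Not emulated: optical point-spread
and defocus blur, chloroplast substructure, uneven illumination beyond what
background flattening removes, and overlapping cells (the generator rejects
overlaps unless explicitly allowed). Segmentation results on these images
therefore bound performance under near-ideal optics only.

**Spectra.** Each species profile is a list of (m/z, relative abundance)
marker ions; peaks are Gaussians of FWHM 0.05 m/z on a dense 0.01 m/z
simulation grid (finer than the 0.1 analysis bin). Ion m/z values are
computed from elemental formulas at run time — galactolipids and
phosphatidylcholines as [M+NH₄]⁺ (the usual positive-ESI adduct for these
neutral lipids; their protonated forms would partly fall below m/z 700),
pigments as [M+H]⁺. Relative abundances are free parameters with documented
defaults chosen so both classes share the three pigment ions (chlorophyll
*b* three times stronger in *Phacus*) while the lipid complement is
class-specific; the resulting binned class means have cosine similarity
≈ 0.48. Cell-to-cell compositional variation is modelled as log-normal
abundance jitter (σ = 0.15) and detector noise as additive Gaussian counts
per channel, floored at zero. The working signal level is "apex SNR":
the ratio of the tallest noiseless peak to the channel noise SD; 10 is the
default study condition. Not emulated: isotope envelopes, unassigned
background lipids, adduct competition, matrix/suppression effects — so a
perfect LOOCV score here shows the pipeline is correct and the marker set
separable, not that real cells are this easy.

**Runs.** A timed run is baseline scans (baseline TIC spread uniformly over
channels) plus one transient burst per cell: a Gaussian time envelope of
σ = 2 scan periods (0.1 s), truncated at ±6σ, scaled so the apex scan
carries the full event spectrum. Events must be separated by more than one
full envelope width. The simulated experiment paces cells at a fixed 2 s
dwell — enough for events to be fully resolved at the default envelope while
keeping a 100-cell run around 4,000 scans; real instrument pacing is a
hardware property that this package does not model.

## Cell recognition

The segmentation stack is deliberately minimal and standard: grey-closing
background estimation (square structuring element, default 35 px) and
subtraction; Otsu threshold on the flattened image; morphological opening
with a disk of radius max(1, 0.2 · minimum expected cell radius); hole
filling; 8-connected labeling; exclusion of border-touching components
(their boundaries are incomplete, and only fully visible cells are sampled);
outer-contour polygonization at the 0.5 level with ≤ 0.5 px simplification.
Filters are applied to the polygon's area and circularity 4πA/P² (capped at
1). Presets: algae 20–700 µm², circularity ≥ 0.5; onion 2,000–10⁶ µm²,
circularity ≥ 0.2. Cells are reported sorted by centroid (y, then x) for
determinism. A watershed split of touching blobs is intentionally absent:
the generator keeps cells disjoint, and overlapping-cell resolution is out
of scope.

Isolation filtering keeps a cell iff no other cell's polygon intersects its
outline dilated by the margin — the single-cell guarantee for cut-and-drop
sampling. It is monotone in the margin by construction.

Field-of-view tiling steps by `fov · (1 − overlap)` in row-major serpentine
order; the last row/column may overshoot the requested region rather than
shrink, so coverage is guaranteed.

## Path planning

**Raster.** Horizontal chords of the inward-inset polygon (default inset
2 µm keeps ablation away from neighbours) at y = y_min + k·spacing, linked
in boustrophedon order; spacing defaults to a 5 µm laser spot. Where the
nominal first or last line is tangent to a smooth outline (zero-length
chord) or stops more than half a spacing short of the top, one extra chord
is inserted half a spacing inside the extreme — without it the end caps of
elliptical cells would miss a few percent of area; with it the
spot-diameter swath covers ≥ 99% of the inset region while all waypoints
stay strictly inside the original outline. An inset that annihilates the
polygon raises a too-small-to-raster error.

**Cut-and-drop.** The contour is the polygon buffered outward by the margin
(default 3 µm for ~10 µm algae) with round joins, 16 arc segments per
quadrant — round joins avoid miter spikes on sharp vertices, and the arc
discretization keeps offset perimeter and area within 1% of the analytic
values for convex shapes. The closed loop is emitted n_passes times
(default 2, enough nominal passes for a 4 µm PEN membrane); puncture and
eject shots are placed at the polygon's area centroid, falling back to the
nearest interior point for non-convex outlines whose centroid lies outside.

Cell visiting order is a greedy nearest-neighbour tour from the slide
origin with ties broken by cell id — deterministic and in practice far
shorter than arbitrary id order, though not optimal.

## MS processing

Event detection thresholds the total-ion chronogram at
median + k·MAD (k = 5) over the whole run; contiguous supra-threshold
regions closer than min_gap = 1 s are merged, and windows are padded by half
a scan interval so single-scan events have width. The per-cell spectrum is
the **sum** (not average) of in-window scans — summing preserves counts for
low-signal single cells — minus the per-channel median of out-of-event
scans, once per summed scan, floored at zero. When many events share a run
the baseline median is computed once over scans outside every detected
window.

Mass recalibration matches each lock mass (default: the three pigment ions
present in both classes) to the nearest observed peak centroid within
tolerance (0.2 m/z); peak centroids are intensity-weighted means over ±10
samples around local maxima, wide enough to keep truncation bias near 1e-4
m/z. Two or more matches give a least-squares linear map observed →
reference, one match a constant offset, zero matches an unchanged spectrum
with a warning flag.

## Classification

PCA is by SVD of the column-mean-centred matrix with no variance scaling
(all features are already on the shared total-ion scale); loading signs are
fixed so each component's largest-magnitude element is positive; explained
fractions are component variance over total variance. k = 2 by default —
on both the synthetic data and by design, additional components add noise
directions, not class separation.

The discriminant is Fisher's: w ∝ S_w⁻¹(μ₁ − μ₂) on the k-dimensional
scores, with pooled within-class covariance (ridge 1e-8·trace added only if
its condition number exceeds 1e12), equal class priors and the threshold at
the midpoint of the projected class means — matching a balanced 50/50
training design. Classes are ordered alphabetically, the first class
projects positive, and an exact tie at the threshold goes to the first
class. Fewer than two members in a class is an error.

LOOCV refits PCA *and* LDA inside every fold. Refitting only the LDA on
fixed global PCA scores would leak the held-out row's contribution to the
projection; the leakage-free variant is the statistically correct one and
is what the reported accuracies mean. On the synthetic two-class data the
distinction is immaterial (both give 100%), but the refit is the contract.

Apportionment centres test rows with the *training* mean, projects on the
training loadings and applies the training discriminant; score coordinates
are returned for plotting. Training rows re-projected this way reproduce
the training scores to 1e-10 (affine consistency).

## Problem sizes and determinism

The shipped tests and the acceptance script use: 50 + 50 training and
60 + 40 test cells (the study design), 12-cell scenes for segmentation
scoring (20 seeds, ~10% area density, SNR 10), 100-cell simulated runs of
~4,000 scans × 30,000 channels held as float32. All randomness flows
through explicitly seeded `numpy.random.Generator` objects; a pipeline run
with the same config and seed yields a byte-identical manifest hash.

## Known limitations

* Segmentation assumes dark, convex-ish, non-overlapping cells on a bright
  background; irregular animal-cell shapes and touching cells are out of
  scope (no watershed by default, no overlap resolution).
* The explained-variance split over PC1/PC2 depends strongly on the
  noise model; with i.i.d. channel noise most variance is isotropic, so the
  fractions are small even when classes separate perfectly. Real spectra
  with correlated biological variation concentrate far more variance in the
  leading components.
* The raster convention is parallel horizontal serpentine lines; concentric
  contour rastering is not implemented.
* The mzML writer emits a minimal, uncompressed MS1-only document; the
  reader handles uncompressed or zlib 32/64-bit float arrays but not the
  full breadth of vendor mzML.
* Event pairing between planned cells and detected bursts is positional
  (i-th planned cell ↔ i-th event), which is exact for the simulated pacing
  but would need retention-time bookkeeping on a real instrument.
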