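# Methods

## Coordinate and sampling conventions

Arrays are stored in numpy plane/row/column order — a volume is indexed
`[z, y, x]`, an xz slice `[z, x]` — while the API speaks the anatomical
convention: x = anterior–posterior (width), y = apical–basal (length),
z = dorsal–ventral (depth), spacing `(sx, sy, sz)` in μm/voxel. Physical
positions are voxel centers: voxel *i* is centered at `(i + 0.5)·s`, ROIs
are half-open in μm, so adjacent ROIs tile an image with no pixel counted
twice. Default voxel spacing is 0.2 × 0.2 × 0.5 μm (x, y, z), typical of
40× confocal sampling. Apical is the minimum-y end after alignment
(configurable via `apical_is_min_y`).

## Cell-shape measurement

A cell is aligned by rotating the xy planes so that the principal axis of
its xy projection (second central moments) is parallel to y; label volumes
are resampled nearest-neighbor, intensity stacks bilinearly. Cell length is
`(max y − min y + 1 voxel)·sy` over the cell's voxels. Digital slices are
single voxel planes at 1/6 and 5/6 of the length from the apical surface —
the section points immediately inside each surface when the length is
divided into six equal sections (5–7 μm inside for 30–42 μm cells). An
optional y-averaging window (`slice_average_planes`) exists for noisy data
but is off by default.

**Chord metrics.** Candidate chord endpoints are boundary pixels (mask
pixels with a 4-neighbor outside). A chord is in-mask when every pixel of
the *supercover* rasterization of the segment between the endpoint centers
is in the mask; the supercover is computed by an exact integer
grid-traversal, is endpoint-symmetric, and includes all four cells at an
exact corner crossing. Chord length is the Euclidean distance between the
endpoint centers **plus the extent of one pixel along the chord direction**
(`|ux|·sx + |uz|·sz`): with this convention a one-pixel-wide bar of n
pixels measures `n·s` and a filled square of side s measures `s√2` along
its diagonal — the values a line tool reports on the continuous
pixel-square geometry. Angles are computed in physical μm, so anisotropic
pixel spacing is handled. Ties break toward the smaller angle, then toward
lexicographically smaller endpoints; the search visits candidates in
length-descending order and is exactly equivalent to exhaustive
enumeration (verified against an independent brute force on random blobs).

The depth chord is constrained to directions within 45° of the z-axis,
*inclusive* ("within 45°" read as ≤; the square-diagonal case makes the
choice observable). Width is measured perpendicular to the realized depth
chord (`width_mode="perpendicular"`); since strict perpendicularity is not
realizable by pixel pairs for oblique depth chords, candidates are gated to
within `width_perp_tol_deg` (default 3°) of the perpendicular, ties broken
toward the smaller angular deviation, with a single-pixel-extent fallback.
The literal x-axis reading (`width_mode="x_axis"`) is available; the two
coincide when the depth chord is z-aligned. The anisotropy flag uses
|ratio − 1| > 0.05 by default; the cutoff is a config value, as no numeric
threshold is standard.

**Tissue fold angle.** Given ordered basal-surface points and a vertex
index, a total-least-squares line (principal eigenvector of the scatter
about the vertex) is fitted to the points within `mhb_fit_span_um`
(default 20 μm, fixed for reproducibility) on each side; the angle between
the two directions, each oriented away from the vertex, lies in (0°, 180°].
Collinear points give 180°.

## Synthetic epithelium

The generator builds a single-layer folded epithelium: two flat sheets of
parallel columnar cells tilted toward each other so their basal anchors lie
on a V with interior angle `fold_angle` (default 90°), plus a vertical
vertex cell whose basal end sits at the V's vertex. Each cell is a prism
along its own apical–basal axis with an elliptical cross-section
perpendicular to that axis: depth (z) is constant (default 12 μm) and
width varies linearly in the axial coordinate, **anchored so that
width/depth equals `apical_xz_ratio` at the 1/6 plane and `basal_xz_ratio`
at the 5/6 plane** — the planes where the analysis slices — making the
recorded ground truth exact at the measurement positions. Straight prisms
of fixed width cannot tile a sharp corner without crossing the midline, so
sheet cells keep the geometric stand-off `v ≥ (x_clear + L·sin ε)/cos ε +
w/2` (ε the sheet tilt) from the vertex; real vertex cells taper and bend,
which is deliberately not modeled — the vertex is instead covered by the
dedicated vertical cell. Cells are painted with an explicit collision
check; any overlap raises.

The membrane channel is the label-boundary shell (thickness 0.4 μm via a
Euclidean distance transform when thicker than one voxel), blurred by a
Gaussian PSF (σ 0.3 μm), peak-normalized to 100 intensity units, plus
additive Gaussian noise — so SNR = 100/`noise_sd`, with noise_sd = 10
(SNR 10) by default. Noise is additive Gaussian rather than Poisson; the
membrane channel is produced for realism and round-trip testing, while
shape measurements run on the label volume (segmentation is an input to
the pipeline, not a contribution). The ground truth includes the basal V
polyline quantized to voxel centers, which is what the fold-angle
measurement consumes.

What passing the recovery tests shows: alignment, slicing and the chord
search recover constructed cross-sections through voxelization, rotation
resampling and the fold geometry. What it does not show: robustness to
segmentation errors, membrane-based segmentation itself, curved or
tapering cells, or nuclear crowding in real pseudostratified tissue.

## Synthetic comet movies

Comets are 2D Gaussian blobs (σ 0.35 μm, peak 100) on a 60×50 μm field at
0.2 μm/px, moving ballistically with per-comet speeds drawn from
N(speed, speed_sd²) (defaults 4.5 ± 0.5 μm/min, the physiological regime)
and isotropic directions; frames are 4 s apart for 600 s. A comet whose
center leaves the field is replaced by a fresh one, holding the expected
in-field count (default 30). Background noise is additive Gaussian with
sd = peak/SNR (default SNR 10). Ground truth records every position and
each track's true speed.

**Speed truth is the observable subset.** Because fast comets exit the
analysis ROI sooner, tracks observable for ≥ `min_track_length` frames
inside the 50×40 μm ROI during the 200 s window are slower on average than
the full spawn distribution; recovered mean speeds are therefore compared
against `observable_track_speeds`, the protocol-matched reference.

## Comet pipeline choices

- Movies are cropped to 200 s and 50×40 μm and min-max rescaled to 8-bit
  over the whole retained series, so frames stay mutually comparable.
- **Particle branch (number/size).** The Otsu threshold is computed on a
  working image pre-filtered with a Gaussian at roughly the comet scale
  (`particle_presmooth_um`, default 0.3 μm) and re-quantized to 8-bit. On
  raw frames with additive Gaussian background the global Otsu cut lands
  inside the unimodal background mode and above-threshold pixels
  percolate; real confocal backgrounds are darker and quieter, and the
  matched pre-filter restores the separation the threshold assumes. Touching
  particles are split by an intensity watershed whose markers are connected
  local-maximum components (plateau-safe, ≥0.5 μm apart); merged comet
  pairs were otherwise the dominant count error. Components outside
  [0.05, 5] μm² are discarded. The Otsu primitive itself maximizes
  between-class variance over the 256-bin histogram, ties to the smallest
  cut, and matches exhaustive enumeration exactly.
- **Detection branch (speed).** Normalized LoG response
  `−σ²∇²(G_σ∗I)` with σ = (blob_diameter/2)/√2 (blob diameter 1 μm);
  3×3 local maxima above the fixed quality floor 0.5; one spot per maximum
  plateau; then an automatic Otsu cut on the spot-quality distribution (the
  "auto initial threshold" step), which makes the fixed floor portable
  across intensity scales. Sub-pixel refinement is a per-axis parabolic
  fit, offsets clipped to ±0.5 px.
- **Linking.** Each open track carries its last-step velocity; per frame,
  gated candidate links (≤ `max_link_radius_um`, default 1.5 μm ≈ 3× the
  expected 0.3 μm per-frame displacement) are assigned by minimizing total
  squared distance to the predictions (Hungarian assignment); unmatched
  tracks persist ≤ 2 frames (gap closing); unmatched spots seed tracks.
  `min_track_length` defaults to 5: with length-3 tracks admitted,
  crossing/merge fragments and residual noise chains form short tracks with
  strongly biased speeds (linking ground-truth detections reproduces truth
  exactly, isolating short spurious tracks as the error source); at 5 the
  recovered mean speed sits within ~2% of the observable truth across the
  3–6 μm/min regime.
- Track speed is the mean over consecutive spot pairs of displacement /
  elapsed time, in μm/min; the movie summary is the unweighted mean over
  tracks, with number and size taken from the particle branch — the two
  branches are deliberately independent.

## Intensity operations

The region normalization divides the vertex ROI mean by the **mean of the
two flanking ROI means** (not a pooled-pixel mean; the two differ when ROI
pixel counts differ). Projections are plane means over
`round(z_extent/sz)` consecutive planes (default 10 μm). The
apical/middle/basal polarity boxes are squares of *area* 10 μm² (side
≈ 3.16 μm) centered on the cell axis at fractions 1/6, 1/2, 5/6 of the
length — mirroring the slice convention; both the area reading (vs a
10 μm × 10 μm box) and the fractions are config values because the
protocol does not pin them down. Densitometry consumes pre-integrated band
intensities; gel-image processing is out of scope. All ratios are exactly
scale-invariant.

## Statistics

Welch's t is the closed form with Welch–Satterthwaite df. The multi-group
test is an additive fixed-effects model `value ~ group + batch` — batch is
a fixed block, appropriate for the small batch counts involved — with a
Type-II F for group (extra sum of squares given batch, equal to Type-I
under balance), fitted by least squares on explicit dummy codings;
confounded designs (group aliased with batch) are detected by rank and
rejected. Tukey HSD uses the Tukey–Kramer statistic on the ANOVA error
mean square with p-values from scipy's studentized-range distribution
(accurate far beyond the 1e-6 needed; an independent numerical integration
was not warranted). Post-hoc tests run only when the omnibus p < 0.05.
Replicates (cells, sides) are averaged per embryo before testing — group
sizes are embryo counts — with the aggregation exposed as a config choice.
Calibration: the null rejection rate of the batch-blocked ANOVA is 5 %
(±1.5 % band) over 2000 simulated tables with real batch effects, and
Tukey with k = 2 reproduces the pooled t-test p to < 1e-6.

## Problem sizes and determinism

Default test/driver problem sizes: epithelia with 3 cells per side + the
vertex cell (7 cells, ≈ 500×450×36 voxels), comet movies with 30 comets ×
150 frames analyzed over 50 frames, 200 random masks for the chord oracle,
2000 null tables for ANOVA calibration — chosen so a full run completes in
a couple of minutes on one CPU while keeping sampling error well inside
the tested tolerances. Every stochastic component draws from a named
substream of a single seed; identical seeds give bit-identical fixtures
and results.

## Known limitations

- Cells are straight elliptical prisms; no curvature, tapering, or
  pseudostratified nuclear packing, and sheet cells keep a stand-off from
  sharp fold vertices.
- Segmentation is an input: membrane-based cell segmentation is not
  provided.
- Comet motion is strictly ballistic in 2D; no catastrophe/rescue
  switching, no 3D excursions, no photobleaching.
- The linear-motion linker does one-step constant-velocity prediction, not
  full Kalman smoothing, and does not model track merging/splitting.
- Batch is a fixed effect; mixed-effects models are out of scope.
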