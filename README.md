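# foldshape

Quantification of 3D cell-shape anisotropy, region-normalized fluorescence
intensity, and microtubule plus-end (EB3) comet dynamics in folded
pseudostratified neuroepithelia — the measurements used to characterize
basal constriction at the zebrafish midbrain–hindbrain boundary constriction
(MHBC), packaged as a tested pipeline with a synthetic-data generator that
provides ground truth for every stage.

It is aimed at imaging labs who want these manual Fiji-style measurements
as reproducible, scriptable operations, and at method developers who need a
benchmarked reference implementation with known-truth fixtures.

## What it measures

**Cell-shape anisotropy (x:z ratio).** A confocal stack is rotated in the
xy plane so the apical–basal axis of a cell runs along y; the cell length
L is measured along y and divided into six equal sections; single-voxel
digital slices in the xz plane are taken at L/6 (apical) and 5L/6 (basal)
— about 5–7 μm inside the surfaces of a 30–42 μm cell. On each slice the
pipeline measures, per cell:

- area (pixel count × pixel area),
- depth *z*: the longest in-mask chord whose direction lies within 45°
  (inclusive) of the z-axis,
- width *x*: the longest in-mask chord perpendicular to the depth chord,
- the anisotropy ratio `x:z = width / depth`; values ≠ 1 indicate
  anisotropic (polarized) cell shape.

Chords are searched over boundary-pixel pairs with an exact supercover
insideness test, and the implementation is verified against an exhaustive
brute-force search. The basal tissue fold angle is measured by fitting
total-least-squares lines to the basal surface on each side of the vertex.

**Intensity normalizations.** Mean-intensity ratios that cancel imaging
gain: the vertex-region mean over the average of the two flanking-region
means (`I_MHBC / ((I_mid + I_hind)/2)`, on a 10 μm average projection);
apical/middle and basal/middle box ratios along the cell axis; and
densitometry of a target band over a loading-control band as percent of
control.

**Comet dynamics.** Time-lapse movies (1 frame / 4 s) are cropped to 200 s
and a 50×40 μm region, rescaled to 8-bit, then quantified in two branches:
Otsu thresholding + particle analysis (with watershed splitting of touching
spots) for comet number and size, and normalized Laplacian-of-Gaussian
sub-pixel detection (blob diameter 1 μm) + predictive linear-motion linking
for per-track speeds in μm/min.

**Group statistics.** Welch's t-test for two groups; for more groups a
one-way fixed-effects ANOVA with experimental batch as an additive block
(Type-II F), gated Tukey HSD post-hoc contrasts on the ANOVA error term,
and significance stars (\* p<0.05, \*\* p<0.01, \*\*\* p<0.005). The unit
of analysis is the embryo.

## Worked example

```python
from foldshape.config import PipelineConfig
from foldshape.shape_metrics import measure_all_cells
from foldshape.synthetic_data import EpitheliumParams, generate_epithelium_stack
import numpy as np

params = EpitheliumParams(basal_xz_ratio=0.5, apical_xz_ratio=0.7, seed=11)
stack, labels, truth = generate_epithelium_stack(params)
recs = measure_all_cells(stack, labels, PipelineConfig())
basal = np.median([r.xz_ratio for r in recs if r.surface == "basal"])
apical = np.median([r.xz_ratio for r in recs if r.surface == "apical"])
print(f"median basal x:z {basal:.3f}, apical {apical:.3f}")
```

prints

```
median basal x:z 0.508, apical 0.715
```

i.e. the pipeline recovers the constructed basal ratio 0.5 and apical
ratio 0.7 to within ±0.02 — cells are roughly twice as deep (z) as they
are wide (x) at the basal surface, the hallmark of basal anisotropy at the
fold. Running the numbered drivers in `analysis/` reproduces the full
sweep; `analysis/04_comets.py`, for example, prints

```
true 4.5 μm/min: measured 4.64 (+0.2%), count 22.3/22.4, size 1.63 μm²
true 5.0 μm/min: measured 5.04 (-0.1%), count 22.5/22.7, size 1.63 μm²
contrast 5.0 vs 4.5 μm/min over 10+10 movies: 4.99 vs 4.46, Welch t = 11.58, p = 8.05e-09 ***
```

— comet speeds are recovered within a few percent of the observable-track
truth and a 0.5 μm/min group difference is clearly detected.

A CLI mirrors the same stages on files:

```sh
foldshape simulate epithelium --seed 11 --out fixtures/
foldshape shape --stack fixtures/membrane.tif --labels fixtures/labels.tif --out out/
foldshape comets --movie movie.tif --out out/
foldshape stats --table measurements.csv --metric xz_ratio --out out/
```

## Layout

- `src/foldshape/` — the library: `io_formats`, `synthetic_data`,
  `slice_geometry`, `shape_metrics`, `intensity_metrics`, `comet_tracking`,
  `group_stats`, `config`, `cli`.
- `analysis/` — numbered narrative drivers (simulate → shape → intensity →
  comets → stats) writing tables under `results/`.
- `tests/` — unit, property and end-to-end recovery tests, including the
  brute-force chord and Otsu oracles.
- `docs/methods.md` — models, conventions, parameter defaults, and known
  limitations.
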