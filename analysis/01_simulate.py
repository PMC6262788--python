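#!/usr/bin/env python
"""Generate the synthetic study inputs: a folded-epithelium stack sweep, a
set of comet movies, and a region-intensity fixture.

Image volumes go to scratch/analysis/ (bulky, regenerable); ground-truth
tables go to results/.
"""

from pathlib import Path

import pandas as pd

from foldshape import io_formats
from foldshape.synthetic_data import (CometMovieParams, EpitheliumParams,
                                      generate_comet_movie,
                                      generate_epithelium_stack,
                                      generate_region_intensity_stack)
from foldshape.types import RoiRect

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"
SEED = 11

REGION_LAYOUT = (RoiRect((45.0, 0.0), 40.0, 50.0),
                 RoiRect((0.0, 0.0), 40.0, 50.0),
                 RoiRect((90.0, 0.0), 40.0, 50.0))


def main():
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    # folded epithelia over the basal-ratio sweep (apical fixed at 0.7)
    truth_rows = []
    for basal in (0.4, 0.5, 0.7, 1.0):
        params = EpitheliumParams(basal_xz_ratio=basal, apical_xz_ratio=0.7,
                                  noise_sd=10.0, seed=SEED)
        stack, labels, truth = generate_epithelium_stack(params)
        tag = f"basal{basal}"
        io_formats.write_stack(SCRATCH / f"epithelium_{tag}.tif", stack)
        io_formats.write_labels(SCRATCH / f"labels_{tag}.tif", labels)
        cells = truth["cells"].copy()
        cells.insert(0, "condition", tag)
        truth_rows.append(cells)
        truth["basal_surface"].to_csv(SCRATCH / f"surface_{tag}.csv",
                                      index=False)
    pd.concat(truth_rows).to_csv(RESULTS / "epithelium_truth.csv",
                                 index=False)

    # comet movies: the two speeds of the knockdown contrast
    for speed, tag in ((4.5, "control"), (5.0, "fast")):
        params = CometMovieParams(n_comets=30, speed=speed, speed_sd=0.5,
                                  frame_interval=4.0, seed=SEED)
        movie, truth = generate_comet_movie(params)
        io_formats.write_movie(SCRATCH / f"comets_{tag}.tif", movie)
        truth["tracks"].to_csv(SCRATCH / f"comet_tracks_{tag}.csv",
                               index=False)

    # region-intensity fixture (vertex enriched over flanking regions)
    stack, truth = generate_region_intensity_stack(
        130.0, 100.0, 95.0, REGION_LAYOUT, noise_sd=4.0, seed=SEED)
    io_formats.write_stack(SCRATCH / "regions.tif", stack)
    io_formats.write_roi_csv(SCRATCH / "regions_rois.csv",
                             {"mhbc": REGION_LAYOUT[0],
                              "midbrain": REGION_LAYOUT[1],
                              "hindbrain": REGION_LAYOUT[2]})

    print(f"fixtures written under {SCRATCH} (images) and {RESULTS} (truth)")


if __name__ == "__main__":
    main()
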