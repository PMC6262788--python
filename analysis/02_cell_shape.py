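#!/usr/bin/env python
"""Measure apical/basal cell-shape anisotropy on the simulated epithelia.

For each basal-ratio condition, every cell is aligned, sliced at the 1/6
and 5/6 section points, and its area / depth / width / x:z ratio measured;
the per-condition medians are compared to the constructed truth, and the
tissue fold angle is measured from the basal surface.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from foldshape.config import PipelineConfig
from foldshape.shape_metrics import measure_all_cells, measure_mhb_angle
from foldshape.synthetic_data import EpitheliumParams, generate_epithelium_stack

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SEED = 11


def main():
    RESULTS.mkdir(exist_ok=True)
    cfg = PipelineConfig()
    rows, summary = [], []
    for basal in (0.4, 0.5, 0.7, 1.0):
        params = EpitheliumParams(basal_xz_ratio=basal, apical_xz_ratio=0.7,
                                  noise_sd=10.0, seed=SEED)
        stack, labels, truth = generate_epithelium_stack(params)
        recs = measure_all_cells(stack, labels, cfg)
        for r in recs:
            rows.append(dict(condition=f"basal{basal}", cell_id=r.cell_id,
                             surface=r.surface, area_um2=r.area_um2,
                             depth_um=r.depth_um, width_um=r.width_um,
                             xz_ratio=r.xz_ratio,
                             anisotropic=r.anisotropic))
        med_b = np.median([r.xz_ratio for r in recs if r.surface == "basal"])
        med_a = np.median([r.xz_ratio for r in recs if r.surface == "apical"])
        surf = truth["basal_surface"]
        angle = measure_mhb_angle(surf[["x_um", "y_um"]].to_numpy(),
                                  surf.attrs["vertex_index"]).angle_deg
        summary.append(dict(condition=f"basal{basal}", true_basal=basal,
                            median_basal=med_b, median_apical=med_a,
                            fold_angle_deg=angle))
        print(f"basal {basal}: median basal ratio {med_b:.3f} "
              f"(err {med_b - basal:+.3f}), apical {med_a:.3f}, "
              f"fold angle {angle:.1f}°")
    pd.DataFrame(rows).to_csv(RESULTS / "shape_measurements.csv", index=False)
    pd.DataFrame(summary).to_csv(RESULTS / "shape_recovery.csv", index=False)
    errs = [abs(s["median_basal"] - s["true_basal"]) for s in summary]
    print(f"max |median - truth| over conditions: {max(errs):.3f} "
          f"(recovered within ±0.05: {max(errs) < 0.05})")


if __name__ == "__main__":
    main()
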