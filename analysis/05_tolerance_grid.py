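#!/usr/bin/env python
"""Perspective-tolerance grids: which camera/distance cells stay within 1%?

An FD estimation error only matters for superimposition if it changes the
face's perspective noticeably; the accepted bound is a 1% change in
physiognomical facial height.  This step classifies every estimate with the
near/far projected-scale metric (depth extent 100 mm) and reports, per
camera/lens and distance, the fraction of estimates inside the bound.
"""

from pathlib import Path

from facefd import FaceDepthModel, load_default_priors, tolerance_table
from facefd.io import read_table, write_table

OUT = Path(__file__).resolve().parent.parent / "results"

depth = FaceDepthModel(load_default_priors()["depth_extent_mm"])
for arm in ("dslr", "smartphone"):
    estimates = read_table(OUT / f"estimates_{arm}.csv")
    grid = tolerance_table(estimates, depth, threshold_pct=1.0)
    write_table(OUT / f"tolerance_{arm}.csv", grid)
    n_pass = int(grid["all_pass"].sum())
    print(f"{arm}: {n_pass}/{len(grid)} (camera, distance) cells fully within the "
          f"1% face-height limit -> {OUT / f'tolerance_{arm}.csv'}")
    worst = grid.nsmallest(3, "pass_fraction")[["camera_name", "fd_true_mm", "pass_fraction"]]
    for _, row in worst.iterrows():
        print(f"  worst: {row['camera_name']} @ {row['fd_true_mm'] / 1000:.1f} m "
              f"pass fraction {row['pass_fraction']:.2f}")
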