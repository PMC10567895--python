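#!/usr/bin/env python
"""Estimate the focus distance of every simulated photograph station.

Per station the first usable duplicate of each view is selected; the frontal
image yields an FD estimate from the fissure length directly and calibrates
the real-life pupil-chord-to-stomion length that drives the profile
estimate.  Writes one tidy estimates CSV per study arm.
"""

from pathlib import Path

from facefd import AnatomicalPriors, dslr_camera_specs, estimate_all, load_default_priors, smartphone_camera_specs
from facefd.io import read_measurements, write_table

OUT = Path(__file__).resolve().parent.parent / "results"

raw = load_default_priors()
priors = AnatomicalPriors(raw["mean_pfl_mm"], raw["sd_pfl_mm"])

for arm, cameras in (("dslr", dslr_camera_specs()), ("smartphone", smartphone_camera_specs())):
    measurements = read_measurements(OUT / f"measurements_{arm}.csv")
    estimates = estimate_all(measurements, cameras, priors)
    write_table(OUT / f"estimates_{arm}.csv", estimates)
    within_10pct = (
        (estimates["fd_est_mm"] / estimates["fd_true_mm"] - 1).abs() <= 0.10
    ).mean()
    print(f"{arm}: {len(estimates)} estimates from {len(measurements)} measurements; "
          f"{100 * within_10pct:.1f}% within 10% of ground truth "
          f"-> {OUT / f'estimates_{arm}.csv'}")
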