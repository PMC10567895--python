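#!/usr/bin/env python
"""Simulate landmark pixel measurements for both study arms.

Ten synthetic participants are drawn with palpebral fissure length ~
Normal(30.7, 1.2) mm and pupil-chord-to-stomion ~ Normal(65, 3.5) mm; every
design row from step 01 is projected through the pinhole model of its
camera/lens and corrupted with 0.5 px Gaussian landmark jitter plus
whole-pixel quantization.  Outputs one measurement CSV per arm.
"""

from pathlib import Path

import numpy as np

from facefd import (
    AnatomicalPriors,
    NoiseModel,
    build_dslr_design,
    build_smartphone_design,
    dslr_camera_specs,
    load_default_priors,
    sample_subjects,
    simulate_measurements,
    smartphone_camera_specs,
)
from facefd.io import write_measurements

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 2023
N_PARTICIPANTS = 10

raw = load_default_priors()
priors = AnatomicalPriors(raw["mean_pfl_mm"], raw["sd_pfl_mm"])
noise = NoiseModel(landmark_jitter_sd_px=0.5, quantize=True)
ss = np.random.SeedSequence(SEED)
subj_seed, dslr_seed, phone_seed = (int(s) % (2**31) for s in ss.generate_state(3))

subjects = sample_subjects(
    N_PARTICIPANTS, priors, raw["pcs_mean_mm"], raw["pcs_sd_mm"], seed=subj_seed
)
print(f"{len(subjects)} subjects; fissure lengths "
      f"{min(s.pfl_true_mm for s in subjects):.1f}-{max(s.pfl_true_mm for s in subjects):.1f} mm")

dslr_meas = simulate_measurements(
    build_dslr_design(N_PARTICIPANTS), subjects, dslr_camera_specs(), noise, seed=dslr_seed
)
phone_meas = simulate_measurements(
    build_smartphone_design(
        N_PARTICIPANTS, dropouts=[(9, "Oppo A57|back"), (10, "iPhone XR|back")]
    ),
    subjects,
    smartphone_camera_specs(),
    noise,
    seed=phone_seed,
)

write_measurements(OUT / "measurements_dslr.csv", dslr_meas, seed=SEED)
write_measurements(OUT / "measurements_smartphone.csv", phone_meas, seed=SEED)
print(f"DSLR arm: {len(dslr_meas)} measurements -> {OUT / 'measurements_dslr.csv'}")
print(f"smartphone arm: {len(phone_meas)} measurements -> {OUT / 'measurements_smartphone.csv'}")
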