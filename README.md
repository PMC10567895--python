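# facefd

Focus-distance estimation from photographed faces, for forensic
craniofacial superimposition.

## The problem

When a skull is compared against an antemortem face photograph, the
postmortem photograph of the skull must be taken from the same camera
vantage point, because the subject-to-camera distance — the **focus distance
(FD)**, measured from the camera's image receptor plane to the exocanthion —
is the sole determinant of perspective distortion for a centred face.
Estimating the FD of an existing photograph is therefore a prerequisite for
a valid superimposition, and `facefd` implements the similar-triangles
estimator that makes this practical, together with a synthetic
photogrammetric validation study, error statistics, and a
perspective-tolerance check.

## The model

A fronto-parallel facial length `L` (mm) photographed at distance `d`
through a lens of focal length `f` (mm) on a sensor with pixel pitch `y`
(mm) spans `x = f·L / (d·y)` pixels. Inverting:

```
FD = f · A / (x · y)
```

* **Frontal views** use the palpebral fissure length (endocanthion to
  exocanthion): its population SD is only 1.2 mm, so the population mean
  `A` (default 30.7 mm, Farkas-style adult norm, configurable) can stand in
  for the unknown individual value.
* **Profile views** lack the fissure. The vertical pupil-chord-to-stomion
  (PCS) distance is calibrated in real-life mm from a frontal photograph of
  the same subject (`PCS_mm = A · pcs_px / pfl_px`) and then drives the same
  inversion on the profile image.

Two reference-plane conventions are available: `simple` (object distance ≡
FD, the default) and `thin_lens` (FD split into object and image distance
via `1/f = 1/d + 1/v`); they differ by roughly `2f`.

An FD error is judged by the perspective change it implies: the near/far
projected-scale ratio `(FD + δ)/FD` with face depth extent `δ` (default
100 mm), bounded at a 1% change in physiognomical facial height.

## Worked example

A frontal photograph from a full-frame body (pixel pitch 6.55 μm) with a
100 mm prime, fissure measured at 458.02 px and PCS at 970.15 px; the paired
profile photograph has PCS = 965.30 px:

```python
from facefd import (AnatomicalPriors, dslr_camera_specs, estimate_fd_frontal,
                    estimate_pcs_mm_from_frontal, estimate_fd_profile)

cam = dslr_camera_specs()["Canon EOS 6D|prime_100"]
priors = AnatomicalPriors(mean_pfl_mm=30.7, sd_pfl_mm=1.2)

estimate_fd_frontal(458.02, cam, priors).fd_mm            # 1023.32 mm
pcs_mm = estimate_pcs_mm_from_frontal(458.02, 970.15, priors)  # 65.03 mm
estimate_fd_profile(965.30, pcs_mm, cam).fd_mm            # 1028.46 mm
```

Both views recover the true 1 m distance to within ~3%, the level set by
how far this subject's fissure sits from the population mean. The implied
perspective change of the profile estimate is 0.25% of facial height — well
inside the 1% superimposition tolerance. The same checks from the shell:

```
$ facefd estimate-frontal --pfl-px 458.02 --camera "Canon EOS 6D|prime_100"
FD = 1023.32 mm (simple)
$ facefd tolerance --fd-true 1000 --fd-est 900 --depth-mm 100
facial height change: 1.0101% -> FAIL
```

## The synthetic validation study

Real validation photographs cannot be redistributed, so
`facefd.simulate` regenerates the study *design* — 10 participants × 3
full-frame DSLR bodies × 5 lens configurations × 6 distances (1–10 m) × 2
views × duplicate exposures (120 photographs per body per participant), plus
a smartphone arm (5 back cameras at 0.3–10 m, 4 front cameras at
0.2–1.3 m) — and simulates landmark pixel measurements through the forward
pinhole model with Gaussian landmark jitter and whole-pixel quantization.
The numbered drivers under `analysis/` run the whole study and write design,
measurement, estimate, error-summary and tolerance tables under `results/`:

```
python analysis/01_build_designs.py
python analysis/02_simulate_measurements.py
python analysis/03_estimate_fd.py
python analysis/04_error_summaries.py
python analysis/05_tolerance_grid.py
```

`facefd run --config <pipeline.yaml>` performs the same end to end.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full synthetic pipeline (both study arms, quantization + 0.5 px
jitter) from the given seed, prints the pooled error statistics and
tolerance-grid pass counts, and writes the results JSON.
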