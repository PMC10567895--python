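# Methods

## Estimator

The estimator treats the camera as an ideal pinhole: a fronto-parallel
length `L` mm at object distance `d` images to `x = f·L/(d·y)` pixels
(`f` focal length mm, `y` pixel pitch mm). Solving for distance with the
population mean palpebral fissure length `A` substituted for the subject's
unknown `L` gives the frontal estimate `FD = f·A/(x·y)`.

Two conventions relate the object distance to the FD, which is defined from
the **image receptor plane**:

* `simple` (default): `d ≡ FD`, the `d ≫ f` approximation. This matches the
  similar-triangles description of the method and is exact to `O(f/FD)`.
* `thin_lens`: `FD = d + v` with `1/f = 1/d + 1/v` and magnification
  `m = v/d = x·y/L`, giving `FD = f·(1+m)²/m`. Forward projection solves
  the quadratic `t² − FD·t + f·FD = 0` for `d` (larger root; requires
  `FD ≥ 4f`, the minimum object-to-sensor separation of a thin lens).
  Inversion rejects `m ≥ 1` (object inside the focal length).

The two differ by roughly `2f` (≤ 0.24 m for the longest fixture lens),
below the anatomical error floor at portrait distances. Neither is asserted
to be "the" published convention — the original formula is not public — so
the variant is recorded in every estimate.

The profile chain calibrates the subject's real pupil-chord-to-stomion
length from a frontal image, `PCS_mm = A·pcs_px/pfl_px`, assuming both
features lie in one fronto-parallel plane, then inverts the projection of
the profile `pcs_px`. Algebraically the noiseless frontal and profile
estimates coincide at `FD_true·A/PFL_true`, which is what the equivalence
tests verify. No pose/foreshortening correction is applied for the partial
(42°) profile rotation by default; `simulate_measurements` exposes a scalar
foreshortening factor (default 1.0) for sensitivity analyses.

### Error structure

With noiseless pixels the signed relative FD error is exactly
`A/PFL_true − 1`: the method's floor is anatomical, about
`0.8·sd/A ≈ 3.1%` MAE on average for `sd = 1.2 mm`, `A = 30.7 mm`, identical
at every distance. Pixel-level noise adds a term proportional to
`σ_px/x`, and since `x ∝ f/(FD·y)`, this term grows linearly with distance
and inversely with focal length — the mechanism behind the rising error at
long FD and the especially poor wide-angle (24 mm) behaviour beyond 6 m
that the simulation reproduces.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| `mean_pfl_mm` (A) | 30.7 | mm | Farkas-style adult ex–en norm; required config, override for sex/ancestry-specific means |
| `sd_pfl_mm` | 1.2 | mm | reported population SD that justifies the mean-as-proxy |
| `pcs_mean_mm` / `pcs_sd_mm` | 65.0 / 3.5 | mm | nominal adult pupil-line-to-stomion prior, generator only (the estimator calibrates PCS per subject) |
| `landmark_jitter_sd_px` | 0.5 | px | sub-pixel landmark placement error consistent with two-decimal on-screen measurement |
| `quantize` | true | — | whole-pixel rounding; the resolution floor that dominates at long FD |
| `depth_extent_mm` (δ) | 100 | mm | nominal near-to-far axial face depth for the perspective metric (artifact definition, see below) |
| `threshold_pct` | 1.0 | % | accepted face-height change bound for superimposition |

All internal lengths are millimetres; CLI options accept `m`/`mm`/`um`
suffixes and convert at the boundary.

## Perspective-tolerance metric

The accepted criterion — "≤ 1% change in physiognomical facial height" — has
no public formula, so this package *defines* its metric: perspective is
summarised by the projected-scale ratio of the nearest to farthest
face-height feature, `r(FD) = (FD + δ)/FD`, and an estimate is acceptable
when `100·|r(FD_est)/r(FD_true) − 1| ≤ 1`. The metric is zero iff the
estimate is exact, strictly increasing in the FD gap, and flattens with
distance (long-FD estimates pass more easily, matching the observed
pattern). δ and the metric itself are declared stand-ins, not
reconstructions of the original operationalisation.

The threshold comparison is inclusive (`≤`).

## Synthetic study generator

The generator emulates the validation *design*, not the photographs:

* subjects: `PFL ~ Normal(A, 1.2)`, `PCS ~ Normal(65, 3.5)`, redrawn on
  non-positive draws (probability ~0 at these priors);
* DSLR arm: 3 full-frame bodies (pixel pitches 6.55/5.67/5.90 μm) × 5 lens
  configurations (primes 50/85/100–105 mm; zoom at 24 and 105–120 mm) ×
  distances {1,2,3,4,6,10} m × frontal+profile × 2 replicates;
* smartphone arm: 5 back cameras (f 3.46–5.53 mm, pitch 1.1–1.6 μm) at
  {0.3,0.5,0.7,1,2,4,6,10} m and 4 front cameras at
  {0.2,...,0.7,0.9,1.1,1.3} m, with optional (participant, camera) dropout
  blocks emulating missing photographs;
* noise applied to the *derived pixel lengths* (jitter then quantization),
  not to 2D landmark coordinates — a documented simplification sufficient
  to reproduce the error structure;
* duplicate handling: both replicates are generated and the estimation
  pipeline keeps the first usable one per station (noise is i.i.d., so the
  rule is unbiased); blinking/unusable frames are not modelled.

What a green simulation test does **not** establish: performance on real
photographs. The generator contains no landmark mis-identification at low
resolution, no optical blur or JPEG artefacts, no lens distortion, no
smartphone image-pipeline manipulation (e.g. pixel binning), and no true 3D
pose geometry. Real-world error levels are therefore expected to exceed the
simulated ones; the simulation validates the estimator's algebra, its
noise-propagation behaviour and the protocol bookkeeping.

## Numerical choices

* Estimates are kept unrounded internally; the CLI prints two decimals.
* Quantized pixel lengths are floored at 1 px (a feature can't vanish);
  simulated lengths are additionally floored at 1e-6 px to keep downstream
  geometry valid under extreme jitter.
* `SEE = sqrt(Σe²/n)` about the ground truth (no regression is fitted); an
  `(n−2)`-denominator variant is available via `see_ddof=2`.
* `MAE%` is the mean of per-observation `100·|e|/FD_true`, not
  `MAE/mean(FD)`.
* Mean signed error keeps the `estimate − truth` sign convention, so
  systematic underestimation is negative.
* All randomness flows from one seed through `numpy.random.SeedSequence`
  children; no global RNG state is touched.
* Pixel pitches outside 0.5–20 μm are rejected at load as physically
  implausible (they usually indicate μm/mm confusion).

## Known limitations

* The fronto-parallel PCS assumption ignores profile foreshortening; the
  optional scalar factor is a sensitivity hook, not a pose model.
* The 35 mm-equivalent conversion trusts the caller's sensor diagonal;
  manufacturer "crop factor" values are deliberately not accepted.
* EXIF reading returns only the actual `FocalLength` tag and never infers
  a focal length from `FocalLengthIn35mmFilm` without an explicit diagonal.
* Groups with a single estimate report SEE but no variance-style
  alternatives.
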