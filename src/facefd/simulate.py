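"""Synthetic photogrammetric study generator.

Real validation photographs are not distributable, so this module emulates
the acquisition design of the two validation studies as landmark *pixel
measurements* rather than rendered images:

* subjects are drawn with palpebral fissure length ~ Normal(A, 1.2 mm) and an
  independent pupil-chord-to-stomion length;
* the DSLR design crosses participants x camera bodies x five lens
  configurations (three primes plus the zoom at its min and max focal
  length) x six distances {1,2,3,4,6,10} m x two views x two replicates —
  120 photographs per body per participant, 360 across three bodies;
* the smartphone design uses each phone's front camera at nine short
  distances (0.2-1.3 m) and back camera at eight distances (0.3-10 m), with
  optional (participant, camera) dropouts emulating missing photographs;
* measurement noise is applied to the *derived pixel lengths* (Gaussian
  landmark jitter, optional rounding to the pixel grid), a simplification
  that reproduces the error structure without modelling 2D landmarks.

Profile pose is not modelled geometrically: PCS is treated as fronto-parallel
in both views, with an optional scalar foreshortening factor for sensitivity
analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import yaml

from .camera import CameraSpec
from .errors import ConfigError
from .estimation import AnatomicalPriors, Measurement

_VIEWS = ("frontal", "profile")


@dataclass(frozen=True)
class SyntheticSubject:
    subject_id: str
    pfl_true_mm: float
    pcs_true_mm: float
    seed: int

    def __post_init__(self) -> None:
        if not (np.isfinite(self.pfl_true_mm) and self.pfl_true_mm > 0):
            raise ConfigError("pfl_true_mm must be finite and > 0")
        if not self.pcs_true_mm > 0:
            raise ConfigError("pcs_true_mm must be > 0")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise applied to each projected pixel length.

    ``landmark_jitter_sd_px`` is the SD of Gaussian jitter emulating landmark
    placement error; ``quantize`` rounds to the whole-pixel grid, emulating
    the resolution floor that dominates at long distances and short focal
    lengths.
    """

    landmark_jitter_sd_px: float = 0.0
    quantize: bool = False

    def __post_init__(self) -> None:
        if self.landmark_jitter_sd_px < 0:
            raise ConfigError("landmark_jitter_sd_px must be >= 0")

    @property
    def enabled(self) -> bool:
        return self.quantize or self.landmark_jitter_sd_px > 0


@dataclass(frozen=True)
class DesignRow:
    """One planned photograph: who, with what, from where."""

    participant_id: int
    camera_name: str
    lens_label: str
    focal_length_mm: float
    distance_mm: float
    view: str
    replicate: int


# ---------------------------------------------------------------------------
# fixture configs


def _load_packaged_yaml(name: str) -> dict:
    with resources.files("facefd.data").joinpath(name).open("r") as fh:
        return yaml.safe_load(fh)


def load_dslr_study_config() -> dict:
    """Packaged DSLR bodies/lenses/distances fixture."""
    return _load_packaged_yaml("dslr_study.yaml")


def load_smartphone_study_config() -> dict:
    """Packaged smartphone cameras/distances fixture."""
    return _load_packaged_yaml("smartphone_study.yaml")


def load_default_priors() -> dict:
    """Packaged anatomical priors (A, SD, PCS prior, depth extent)."""
    return _load_packaged_yaml("priors.yaml")


def dslr_camera_specs(config: Optional[dict] = None) -> Dict[str, CameraSpec]:
    """One :class:`CameraSpec` per body|lens combination, keyed by name."""
    config = config or load_dslr_study_config()
    specs: Dict[str, CameraSpec] = {}
    for body in config["bodies"]:
        y_mm = body["pixel_size_um"] / 1000.0
        w_mm, h_mm = body["sensor_mm"]
        diag = float(np.hypot(w_mm, h_mm))
        for lens in body["lenses"]:
            name = f"{body['name']}|{lens['label']}"
            specs[name] = CameraSpec(
                name=name,
                focal_length_mm=float(lens["focal_length_mm"]),
                pixel_size_mm=y_mm,
                sensor_diagonal_mm=diag,
            )
    return specs


def smartphone_camera_specs(config: Optional[dict] = None) -> Dict[str, CameraSpec]:
    """One :class:`CameraSpec` per phone|facing combination, keyed by name."""
    config = config or load_smartphone_study_config()
    specs: Dict[str, CameraSpec] = {}
    for phone in config["phones"]:
        for facing in ("front", "back"):
            cam = phone.get(facing)
            if cam is None:
                continue
            name = f"{phone['name']}|{facing}"
            specs[name] = CameraSpec(
                name=name,
                focal_length_mm=float(cam["focal_length_mm"]),
                pixel_size_mm=cam["pixel_size_um"] / 1000.0,
            )
    return specs


# ---------------------------------------------------------------------------
# design builders


def build_dslr_design(
    n_participants: int = 1,
    config: Optional[dict] = None,
    replicates: int = 2,
) -> List[DesignRow]:
    """Cartesian DSLR acquisition design, in deterministic row order.

    participants x bodies x lens configs x distances x views x replicates;
    with the packaged fixture (3 bodies, 5 lens configs, 6 distances) one
    participant yields 120 rows per body, 360 in total.
    """
    if n_participants < 1 or replicates < 1:
        raise ConfigError("n_participants and replicates must be >= 1")
    config = config or load_dslr_study_config()
    bodies = config.get("bodies") or []
    if not bodies:
        raise ConfigError("DSLR design needs at least one camera body")
    distances_mm = [1000.0 * d for d in config["distances_m"]]
    rows: List[DesignRow] = []
    for pid in range(1, n_participants + 1):
        for body in bodies:
            for lens in body["lenses"]:
                for dist in distances_mm:
                    for view in _VIEWS:
                        for rep in range(1, replicates + 1):
                            rows.append(
                                DesignRow(
                                    participant_id=pid,
                                    camera_name=f"{body['name']}|{lens['label']}",
                                    lens_label=lens["label"],
                                    focal_length_mm=float(lens["focal_length_mm"]),
                                    distance_mm=dist,
                                    view=view,
                                    replicate=rep,
                                )
                            )
    return rows


def build_smartphone_design(
    n_participants: int,
    config: Optional[dict] = None,
    replicates: int = 2,
    dropouts: Iterable[Tuple[int, str]] = (),
) -> List[DesignRow]:
    """Smartphone acquisition design with optional per-(participant, camera) dropouts.

    Front cameras are exercised at the short-range distance set, back cameras
    at the long-range set.  ``dropouts`` removes every row of a
    (participant_id, camera_name) pair, emulating participants with missing
    photographs for one camera.
    """
    if n_participants < 0 or replicates < 1:
        raise ConfigError("n_participants must be >= 0 and replicates >= 1")
    config = config or load_smartphone_study_config()
    phones = config.get("phones") or []
    if not phones:
        raise ConfigError("smartphone design needs at least one phone")
    dist_sets = {
        "front": [1000.0 * d for d in config["front_distances_m"]],
        "back": [1000.0 * d for d in config["back_distances_m"]],
    }
    known: Set[str] = {
        f"{p['name']}|{facing}" for p in phones for facing in ("front", "back") if p.get(facing)
    }
    drop: Set[Tuple[int, str]] = set(dropouts)
    for _, cam in drop:
        if cam not in known:
            raise ConfigError(f"dropout references unknown camera {cam!r}")
    rows: List[DesignRow] = []
    for pid in range(1, n_participants + 1):
        for phone in phones:
            for facing in ("front", "back"):
                cam = phone.get(facing)
                if cam is None:
                    continue
                name = f"{phone['name']}|{facing}"
                if (pid, name) in drop:
                    continue
                for dist in dist_sets[facing]:
                    for view in _VIEWS:
                        for rep in range(1, replicates + 1):
                            rows.append(
                                DesignRow(
                                    participant_id=pid,
                                    camera_name=name,
                                    lens_label=facing,
                                    focal_length_mm=float(cam["focal_length_mm"]),
                                    distance_mm=dist,
                                    view=view,
                                    replicate=rep,
                                )
                            )
    return rows


# ---------------------------------------------------------------------------
# subjects and measurements


def sample_subjects(
    n: int,
    priors: AnatomicalPriors,
    pcs_mean_mm: float = 65.0,
    pcs_sd_mm: float = 3.5,
    seed: int = 0,
) -> List[SyntheticSubject]:
    """Draw ``n`` subjects with Normal fissure and PCS lengths, reproducibly.

    Non-positive draws are redrawn (probability is negligible at the default
    priors but the truncation is explicit).
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    if pcs_sd_mm < 0 or not pcs_mean_mm > 0:
        raise ConfigError("pcs_mean_mm must be > 0 and pcs_sd_mm >= 0")
    rng = np.random.default_rng(seed)

    def _draw(mean: float, sd: float) -> float:
        while True:
            v = rng.normal(mean, sd)
            if v > 0:
                return float(v)

    subjects = []
    for i in range(1, n + 1):
        subjects.append(
            SyntheticSubject(
                subject_id=f"S{i:04d}",
                pfl_true_mm=_draw(priors.mean_pfl_mm, priors.sd_pfl_mm),
                pcs_true_mm=_draw(pcs_mean_mm, pcs_sd_mm),
                seed=int(seed),
            )
        )
    return subjects


def simulate_measurements(
    design: Sequence[DesignRow],
    subjects: Sequence[SyntheticSubject],
    cameras: Dict[str, CameraSpec],
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    foreshortening: float = 1.0,
) -> List[Measurement]:
    """Turn a design into landmark pixel measurements via the forward model.

    Frontal rows record both the fissure and PCS pixel lengths; profile rows
    record PCS only (scaled by ``foreshortening``, default 1.0).  Jitter and
    quantization are applied per length; quantized lengths are floored at one
    pixel.  Reproducible given ``seed`` and the design order.
    """
    from .camera import project_length

    if not 0 < foreshortening <= 1.0:
        raise ConfigError("foreshortening must be in (0, 1]")
    rng = np.random.default_rng(seed)
    out: List[Measurement] = []
    for row in design:
        if not 1 <= row.participant_id <= len(subjects):
            raise ConfigError(
                f"design references participant {row.participant_id} but only "
                f"{len(subjects)} subjects were supplied"
            )
        cam = cameras.get(row.camera_name)
        if cam is None:
            raise ConfigError(f"design references unknown camera {row.camera_name!r}")
        subj = subjects[row.participant_id - 1]

        def _measure(length_mm: float) -> float:
            px = project_length(length_mm, row.distance_mm, cam)
            if noise.landmark_jitter_sd_px > 0:
                px += rng.normal(0.0, noise.landmark_jitter_sd_px)
            if noise.quantize:
                px = max(1.0, float(round(px)))
            return max(px, 1e-6)

        pfl_px = _measure(subj.pfl_true_mm) if row.view == "frontal" else None
        pcs_mm = subj.pcs_true_mm * (foreshortening if row.view == "profile" else 1.0)
        pcs_px = _measure(pcs_mm)
        out.append(
            Measurement(
                subject_id=subj.subject_id,
                camera_name=row.camera_name,
                view=row.view,  # type: ignore[arg-type]
                pfl_px=pfl_px,
                pcs_px=pcs_px,
                fd_true_mm=row.distance_mm,
                replicate_id=row.replicate,
            )
        )
    return out
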