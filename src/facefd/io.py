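"""CSV/YAML readers and writers and the end-to-end synthetic pipeline.

All tabular artifacts are comma-separated UTF-8 with a header row and a
``#``-prefixed provenance header (package version, seed, config hash) that
readers skip.  Distances are millimetres everywhere internally; boundary
helpers convert metre and micrometre inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import __version__
from .camera import CameraSpec, ModelVariant
from .errors import ConfigError, SchemaError
from .estimation import (
    AnatomicalPriors,
    FDEstimate,
    Measurement,
    estimate_fd_frontal,
    estimate_pair,
    select_first_replicate,
)
from .simulate import (
    DesignRow,
    NoiseModel,
    build_dslr_design,
    build_smartphone_design,
    dslr_camera_specs,
    load_default_priors,
    sample_subjects,
    simulate_measurements,
    smartphone_camera_specs,
)
from .tolerance import FaceDepthModel
from .evaluation import summarize, tolerance_table

log = logging.getLogger("facefd")

MEASUREMENT_COLUMNS = [
    "subject_id",
    "camera_name",
    "view",
    "pfl_px",
    "pcs_px",
    "fd_true_mm",
    "replicate_id",
]


def parse_length_mm(text: str) -> float:
    """Parse a length with an optional unit suffix into millimetres.

    Accepts ``"3000"`` / ``"3000 mm"`` / ``"3 m"`` / ``"6.55 um"`` (also
    ``µm``); bare numbers are taken as millimetres.
    """
    s = str(text).strip().lower().replace("µ", "u")
    for suffix, scale in (("um", 1e-3), ("mm", 1.0), ("cm", 10.0), ("m", 1000.0)):
        if s.endswith(suffix):
            return float(s[: -len(suffix)].strip()) * scale
    return float(s)


# ---------------------------------------------------------------------------
# provenance-aware CSV I/O


def _provenance_lines(seed: Optional[int], config_hash: Optional[str]) -> List[str]:
    lines = [f"# facefd {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config_hash is not None:
        lines.append(f"# config_sha256: {config_hash}")
    return lines


def write_table(
    path: str | Path,
    table: pd.DataFrame,
    seed: Optional[int] = None,
    config_hash: Optional[str] = None,
) -> Path:
    """Write a DataFrame as CSV with a commented provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in _provenance_lines(seed, config_hash):
            fh.write(line + "\n")
        table.to_csv(fh, index=False, lineterminator="\n")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table` (provenance lines skipped)."""
    return pd.read_csv(path, comment="#")


def measurements_to_frame(measurements: Sequence[Measurement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": m.subject_id,
                "camera_name": m.camera_name,
                "view": m.view,
                "pfl_px": m.pfl_px,
                "pcs_px": m.pcs_px,
                "fd_true_mm": m.fd_true_mm,
                "replicate_id": m.replicate_id,
            }
            for m in measurements
        ],
        columns=MEASUREMENT_COLUMNS,
    )


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return float(value)


def frame_to_measurements(frame: pd.DataFrame, source: str = "<table>") -> List[Measurement]:
    """Validate a measurement table and convert rows to :class:`Measurement`.

    Missing numeric fields must be empty cells, not zeros.  The ``view``
    column is case-normalized.  Unknown columns are tolerated (pass-through
    at the CSV level) but not carried on the objects.
    """
    missing = [c for c in MEASUREMENT_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{source}: missing required column(s) {', '.join(missing)}")
    out: List[Measurement] = []
    for idx, row in frame.iterrows():
        try:
            rep = _opt_float(row["replicate_id"])
            out.append(
                Measurement(
                    subject_id=str(row["subject_id"]),
                    camera_name=str(row["camera_name"]),
                    view=str(row["view"]).strip().lower(),  # type: ignore[arg-type]
                    pfl_px=_opt_float(row["pfl_px"]),
                    pcs_px=_opt_float(row["pcs_px"]),
                    fd_true_mm=_opt_float(row["fd_true_mm"]),
                    replicate_id=int(rep) if rep is not None else None,
                )
            )
        except (ValueError, KeyError) as exc:
            raise SchemaError(f"{source}: row {idx}: {exc}") from exc
    return out


def read_measurements(path: str | Path) -> List[Measurement]:
    """Read and validate a measurement CSV."""
    return frame_to_measurements(read_table(path), source=str(path))


def write_measurements(
    path: str | Path,
    measurements: Sequence[Measurement],
    seed: Optional[int] = None,
    config_hash: Optional[str] = None,
) -> Path:
    return write_table(path, measurements_to_frame(measurements), seed, config_hash)


def design_to_frame(design: Sequence[DesignRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "camera_name": r.camera_name,
                "lens_label": r.lens_label,
                "focal_length_mm": r.focal_length_mm,
                "distance_mm": r.distance_mm,
                "view": r.view,
                "replicate": r.replicate,
            }
            for r in design
        ]
    )


def read_camera_config(path: str | Path) -> List[CameraSpec]:
    """Load camera specs from a YAML/JSON config.

    Each entry needs ``name``, ``focal_length_mm`` and ``pixel_size_um``
    (converted to mm at load); ``sensor_diagonal_mm`` and
    ``equivalent_focal_length_mm`` are optional — when only the latter is
    given, the actual focal length is derived from the sensor diagonal.
    """
    from .camera import actual_focal_from_equivalent

    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    entries = raw["cameras"] if isinstance(raw, dict) and "cameras" in raw else raw
    if not isinstance(entries, list):
        raise ConfigError(f"{path}: expected a list of camera entries")
    specs: List[CameraSpec] = []
    for entry in entries:
        try:
            name = entry["name"]
            diag = entry.get("sensor_diagonal_mm")
            f_mm = entry.get("focal_length_mm")
            if f_mm is None:
                f35 = entry.get("equivalent_focal_length_mm")
                if f35 is None or diag is None:
                    raise ConfigError(
                        "needs focal_length_mm, or equivalent_focal_length_mm "
                        "plus sensor_diagonal_mm"
                    )
                f_mm = actual_focal_from_equivalent(float(f35), float(diag))
            specs.append(
                CameraSpec(
                    name=name,
                    focal_length_mm=float(f_mm),
                    pixel_size_mm=float(entry["pixel_size_um"]) / 1000.0,
                    sensor_diagonal_mm=float(diag) if diag is not None else None,
                )
            )
        except KeyError as exc:
            raise ConfigError(f"{path}: camera entry missing key {exc}") from exc
    return specs


# ---------------------------------------------------------------------------
# estimation over measurement tables


def estimate_all(
    measurements: Sequence[Measurement],
    cameras: Dict[str, CameraSpec],
    priors: AnatomicalPriors,
    variant: ModelVariant = "simple",
) -> pd.DataFrame:
    """Run the frontal and frontal-calibrated profile estimators over a table.

    Measurements are grouped into stations (subject, camera/lens, ground
    truth FD); per station the first usable replicate of each view is kept,
    frontal/profile pairs are chained, and unpaired frontal images are
    estimated alone.  Profile images without a frontal partner cannot be
    estimated (no PCS calibration) and are dropped with a log message.

    Returns a tidy frame with one row per estimate; ``camera_name`` values of
    the form ``"<body>|<lens>"`` are split into ``camera_body``/``lens_label``
    columns for grouping.
    """
    selected = select_first_replicate(list(measurements))
    stations: Dict[tuple, Dict[str, Measurement]] = {}
    for m in selected:
        stations.setdefault((m.subject_id, m.camera_name, m.fd_true_mm), {})[m.view] = m

    rows: List[dict] = []
    n_unpaired_profiles = 0
    for (subject_id, camera_name, fd_true), views in stations.items():
        cam = cameras.get(camera_name)
        if cam is None:
            raise ConfigError(f"no camera spec for {camera_name!r}")
        frontal, profile = views.get("frontal"), views.get("profile")
        estimates: List[Tuple[FDEstimate, Optional[float]]] = []
        if frontal is not None and profile is not None and (frontal.pcs_px or 0) > 0:
            ef, ep = estimate_pair(frontal, profile, cam, priors, variant)
            estimates = [(ef, None), (ep, ep.inputs_echo["pcs_mm_est"])]
        elif frontal is not None:
            estimates = [(estimate_fd_frontal(frontal.pfl_px, cam, priors, variant), None)]
        else:
            n_unpaired_profiles += 1
            continue
        body, _, lens = camera_name.partition("|")
        for est, pcs_mm in estimates:
            rows.append(
                {
                    "subject_id": subject_id,
                    "camera_name": camera_name,
                    "camera_body": body,
                    "lens_label": lens or None,
                    "view": est.view,
                    "fd_true_mm": fd_true,
                    "fd_est_mm": est.fd_mm,
                    "model_variant": est.model_variant,
                    "pcs_mm_est": pcs_mm,
                }
            )
    if n_unpaired_profiles:
        log.info("dropped %d profile-only stations (no frontal calibration)", n_unpaired_profiles)
    out = pd.DataFrame(rows)
    log.info("estimate_all: %d measurements in, %d estimates out", len(measurements), len(out))
    return out


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """Configuration of the end-to-end synthetic validation pipeline."""

    seed: int = 0
    study: str = "dslr"  # dslr | smartphone | both
    n_participants: int = 10
    replicates: int = 2
    mean_pfl_mm: float = field(default_factory=lambda: load_default_priors()["mean_pfl_mm"])
    sd_pfl_mm: float = 1.2
    pcs_mean_mm: float = 65.0
    pcs_sd_mm: float = 3.5
    landmark_jitter_sd_px: float = 0.5
    quantize: bool = True
    model_variant: ModelVariant = "simple"
    depth_extent_mm: float = 100.0
    threshold_pct: float = 1.0
    dropouts: List[Tuple[int, str]] = field(default_factory=list)
    out_dir: str = "results/pipeline"

    def __post_init__(self) -> None:
        if self.study not in ("dslr", "smartphone", "both"):
            raise ConfigError(f"unknown study {self.study!r}")
        if self.model_variant not in ("simple", "thin_lens"):
            raise ConfigError(f"unknown model_variant {self.model_variant!r}")
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")

    @property
    def priors(self) -> AnatomicalPriors:
        return AnatomicalPriors(self.mean_pfl_mm, self.sd_pfl_mm)

    @property
    def noise(self) -> NoiseModel:
        return NoiseModel(self.landmark_jitter_sd_px, self.quantize)

    @property
    def depth_model(self) -> FaceDepthModel:
        return FaceDepthModel(self.depth_extent_mm)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: pipeline config must be a mapping")
        raw.pop("config_name", None)
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config key(s) {sorted(unknown)}")
        if "dropouts" in raw:
            raw["dropouts"] = [(int(p), str(c)) for p, c in raw["dropouts"]]
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Dict[str, Path]:
    """Run design -> simulate -> estimate -> evaluate -> tolerance, writing CSVs.

    Deterministic given the config (all randomness flows from ``config.seed``
    through per-stage children); returns the artifact paths.  Partially
    written outputs are removed if a stage fails.
    """
    import numpy as np

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    ss = np.random.SeedSequence(config.seed)
    subj_seed, noise_seed = (int(s) % (2**31) for s in ss.generate_state(2))

    design: List[DesignRow] = []
    cameras: Dict[str, CameraSpec] = {}
    if config.study in ("dslr", "both"):
        design += build_dslr_design(config.n_participants, replicates=config.replicates)
        cameras.update(dslr_camera_specs())
    if config.study in ("smartphone", "both"):
        design += build_smartphone_design(
            config.n_participants,
            replicates=config.replicates,
            dropouts=config.dropouts,
        )
        cameras.update(smartphone_camera_specs())
    log.info("design: %d rows", len(design))

    subjects = sample_subjects(
        config.n_participants,
        config.priors,
        config.pcs_mean_mm,
        config.pcs_sd_mm,
        seed=subj_seed,
    )
    measurements = simulate_measurements(design, subjects, cameras, config.noise, seed=noise_seed)
    log.info("simulate: %d measurements", len(measurements))

    estimates = estimate_all(measurements, cameras, config.priors, config.model_variant)
    summary = summarize(estimates, ["camera_name", "view", "fd_true_mm"])
    tol = tolerance_table(estimates, config.depth_model, config.threshold_pct)

    paths: Dict[str, Path] = {}
    written: List[Path] = []
    try:
        for name, frame in (
            ("design", design_to_frame(design)),
            ("measurements", measurements_to_frame(measurements)),
            ("estimates", estimates),
            ("summary", summary),
            ("tolerance", tol),
        ):
            p = write_table(out_dir / f"{name}.csv", frame, config.seed, chash)
            paths[name] = p
            written.append(p)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return paths
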