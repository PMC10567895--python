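"""Focus-distance estimation from facial landmark measurements.

Frontal photographs use the palpebral fissure length (PFL, endocanthion to
exocanthion): its population standard deviation is small (1.2 mm), so the
population mean ``A`` can stand in for a subject's unknown true length.  The
frontal estimate inverts the pinhole projection:

    FD = f * A / (x * y)                      (simple variant)

with ``x`` the measured fissure length in pixels, ``f`` the focal length (mm)
and ``y`` the pixel pitch (mm).

Profile photographs lack the fissure.  There the vertical pupil-chord-to-
stomion distance (PCS) is used: its real-life size is first calibrated from a
frontal photograph of the same subject through the fissure-length scale,
``PCS_mm = A * pcs_px / pfl_px``, and that calibrated length then drives the
same projection inversion on the profile image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Literal, Optional

from .camera import CameraSpec, ModelVariant, invert_projection
from .errors import ConfigError, InvalidMeasurementError, PairingError

View = Literal["frontal", "profile"]


@dataclass(frozen=True)
class AnatomicalPriors:
    """Population priors for the palpebral fissure length.

    ``mean_pfl_mm`` is the "known length" proxy ``A``; ``sd_pfl_mm`` defaults
    to the reported 1.2 mm population standard deviation.
    """

    mean_pfl_mm: float
    sd_pfl_mm: float = 1.2

    def __post_init__(self) -> None:
        if not self.mean_pfl_mm > 0:
            raise ConfigError("mean_pfl_mm must be > 0")
        if self.sd_pfl_mm < 0:
            raise ConfigError("sd_pfl_mm must be >= 0")
        if not self.sd_pfl_mm < self.mean_pfl_mm:
            raise ConfigError("sd_pfl_mm must be smaller than mean_pfl_mm")


@dataclass
class Measurement:
    """Landmark pixel measurements from one photograph.

    ``pfl_px`` (palpebral fissure) is required for frontal views; ``pcs_px``
    (pupil chord to stomion) is measured in both views.  ``fd_true_mm`` is
    the ground-truth focus distance when the acquisition distance is known.
    """

    subject_id: str
    camera_name: str
    view: View
    pfl_px: Optional[float] = None
    pcs_px: Optional[float] = None
    fd_true_mm: Optional[float] = None
    replicate_id: Optional[int] = None

    def __post_init__(self) -> None:
        self.view = self.view.strip().lower()  # type: ignore[assignment]
        if self.view not in ("frontal", "profile"):
            raise InvalidMeasurementError(f"unknown view {self.view!r}")
        if self.view == "frontal" and not (self.pfl_px or 0) > 0:
            raise InvalidMeasurementError(
                f"{self.subject_id}/{self.camera_name}: frontal view requires pfl_px > 0"
            )
        if self.view == "profile" and not (self.pcs_px or 0) > 0:
            raise InvalidMeasurementError(
                f"{self.subject_id}/{self.camera_name}: profile view requires pcs_px > 0"
            )
        if self.fd_true_mm is not None and not self.fd_true_mm > 0:
            raise InvalidMeasurementError("fd_true_mm, if present, must be > 0")


@dataclass(frozen=True)
class FDEstimate:
    """An estimated focus distance (mm) plus the inputs that produced it."""

    fd_mm: float
    model_variant: ModelVariant
    view: View
    inputs_echo: Dict[str, float] = field(default_factory=dict)


def estimate_fd_frontal(
    pfl_px: float,
    camera: CameraSpec,
    priors: AnatomicalPriors,
    variant: ModelVariant = "simple",
) -> FDEstimate:
    """Estimate FD from a frontal photograph's palpebral fissure length."""
    if not pfl_px > 0:
        raise InvalidMeasurementError(f"pfl_px must be > 0, got {pfl_px}")
    fd = invert_projection(pfl_px, priors.mean_pfl_mm, camera, variant)
    return FDEstimate(
        fd_mm=fd,
        model_variant=variant,
        view="frontal",
        inputs_echo={
            "x_px": pfl_px,
            "f_mm": camera.focal_length_mm,
            "A_mm": priors.mean_pfl_mm,
            "y_mm": camera.pixel_size_mm,
        },
    )


def estimate_pcs_mm_from_frontal(
    pfl_px: float, pcs_px: float, priors: AnatomicalPriors
) -> float:
    """Calibrate the real-life pupil-chord-to-stomion length from a frontal image.

    Both pixel lengths must come from the *same* frontal photograph; the
    fissure-length proxy fixes the mm-per-pixel scale, so
    ``PCS_mm = A * pcs_px / pfl_px``.
    """
    if not pfl_px > 0 or not pcs_px > 0:
        raise InvalidMeasurementError(
            f"pixel lengths must be > 0, got pfl_px={pfl_px}, pcs_px={pcs_px}"
        )
    return priors.mean_pfl_mm * pcs_px / pfl_px


def estimate_fd_profile(
    pcs_px_profile: float,
    pcs_mm_est: float,
    camera: CameraSpec,
    variant: ModelVariant = "simple",
) -> FDEstimate:
    """Estimate FD from a profile photograph via the calibrated PCS length."""
    if not pcs_px_profile > 0:
        raise InvalidMeasurementError(f"pcs_px_profile must be > 0, got {pcs_px_profile}")
    if not pcs_mm_est > 0:
        raise InvalidMeasurementError(f"pcs_mm_est must be > 0, got {pcs_mm_est}")
    fd = invert_projection(pcs_px_profile, pcs_mm_est, camera, variant)
    return FDEstimate(
        fd_mm=fd,
        model_variant=variant,
        view="profile",
        inputs_echo={
            "pcs_px": pcs_px_profile,
            "f_mm": camera.focal_length_mm,
            "pcs_mm_est": pcs_mm_est,
            "y_mm": camera.pixel_size_mm,
        },
    )


def estimate_pair(
    frontal: Measurement,
    profile: Measurement,
    camera: CameraSpec,
    priors: AnatomicalPriors,
    variant: ModelVariant = "simple",
) -> tuple[FDEstimate, FDEstimate]:
    """Estimate FD for a same-station frontal/profile photograph pair.

    The pair must share a camera/lens combination (same ``camera_name``); the
    frontal image supplies both the fissure length and the PCS calibration,
    the profile image only its PCS pixel length.  The intermediate
    ``pcs_mm_est`` is echoed in the profile estimate.
    """
    if frontal.view != "frontal" or profile.view != "profile":
        raise PairingError(
            f"expected a (frontal, profile) pair, got ({frontal.view}, {profile.view})"
        )
    if frontal.camera_name != profile.camera_name:
        raise PairingError(
            f"camera mismatch: {frontal.camera_name!r} vs {profile.camera_name!r}"
        )
    if not (frontal.pfl_px or 0) > 0 or not (frontal.pcs_px or 0) > 0:
        raise InvalidMeasurementError(
            "frontal measurement needs both pfl_px and pcs_px for pairing"
        )
    if not (profile.pcs_px or 0) > 0:
        raise InvalidMeasurementError("profile measurement needs pcs_px")
    est_frontal = estimate_fd_frontal(frontal.pfl_px, camera, priors, variant)
    pcs_mm = estimate_pcs_mm_from_frontal(frontal.pfl_px, frontal.pcs_px, priors)
    est_profile = estimate_fd_profile(profile.pcs_px, pcs_mm, camera, variant)
    return est_frontal, est_profile


def select_first_replicate(measurements: list[Measurement]) -> list[Measurement]:
    """Keep the first usable measurement per (subject, camera, view, FD) station.

    Duplicate exposures exist to guard against blinking; absent an image
    quality score the first non-missing replicate is selected, and the rule
    is deliberately explicit rather than implicit in file order.
    """
    seen: dict = {}
    for m in measurements:
        key = (m.subject_id, m.camera_name, m.view, m.fd_true_mm)
        if key not in seen:
            seen[key] = m
    return list(seen.values())
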