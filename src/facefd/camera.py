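"""Camera/lens representation and pinhole projection geometry.

The subject-to-camera distance of interest — the *focus distance* (FD) — is
measured from the camera's image receptor (sensor) plane to the subject, so
two projection conventions are offered:

``simple``
    Similar triangles with the lens-to-object distance taken equal to the FD
    (the ``d >> f`` approximation): a real-world length ``L`` at distance
    ``d`` projects to ``x = f * L / (d * y)`` pixels, where ``f`` is the lens
    focal length and ``y`` the sensor pixel pitch, both in millimetres.

``thin_lens``
    The FD is split into object distance ``d`` and image distance ``v`` with
    ``d + v = FD`` and the thin-lens equation ``1/f = 1/d + 1/v``; the
    magnification is ``v / d``.  The two conventions differ by roughly ``2f``
    in the recovered FD, negligible for portrait distances but exposed so the
    choice is explicit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Tuple

from .errors import ConfigError, InvalidGeometryError

#: Diagonal of the full-frame 36 x 24 mm sensor, used for 35 mm-equivalent
#: focal length conversion.
FULL_FRAME_DIAGONAL_MM: float = math.hypot(36.0, 24.0)  # 43.2666...

#: Physically plausible sensor pixel pitch range, mm (0.5-20 um).
_PIXEL_PITCH_RANGE_MM: Tuple[float, float] = (0.0005, 0.02)

ModelVariant = Literal["simple", "thin_lens"]


@dataclass(frozen=True)
class CameraSpec:
    """Optical and sensor parameters of one camera/lens combination.

    Parameters
    ----------
    name
        Free-text identifier.  Pipelines that combine a camera body with
        several lenses encode the combination as ``"<body>|<lens_label>"``.
    focal_length_mm
        Lens focal length ``f`` in millimetres (the actual focal length, not
        a 35 mm equivalent).
    pixel_size_mm
        Sensor pixel pitch ``y`` in millimetres.  Manufacturer sheets quote
        micrometres; config loaders convert at load time.
    sensor_diagonal_mm
        Optional physical sensor diagonal, needed only to convert 35
        mm-equivalent focal lengths.
    resolution_px
        Optional ``(width, height)`` sensor resolution in pixels.
    """

    name: str
    focal_length_mm: float
    pixel_size_mm: float
    sensor_diagonal_mm: Optional[float] = None
    resolution_px: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        if not self.focal_length_mm > 0:
            raise ConfigError(f"{self.name}: focal_length_mm must be > 0")
        lo, hi = _PIXEL_PITCH_RANGE_MM
        if not (lo <= self.pixel_size_mm <= hi):
            raise ConfigError(
                f"{self.name}: pixel_size_mm={self.pixel_size_mm} outside the "
                f"plausible range [{lo}, {hi}] mm (0.5-20 um)"
            )
        if self.sensor_diagonal_mm is not None and not self.sensor_diagonal_mm > 0:
            raise ConfigError(f"{self.name}: sensor_diagonal_mm must be > 0")


def _thin_lens_object_distance(fd_mm: float, f_mm: float) -> float:
    """Object distance d with d + v = fd and 1/f = 1/d + 1/v.

    d and v are the roots of ``t**2 - fd*t + f*fd = 0``; the larger root is
    the object distance for magnification < 1.  Requires ``fd >= 4f`` (the
    minimum sensor-to-object separation of a thin lens).
    """
    disc = fd_mm * fd_mm - 4.0 * f_mm * fd_mm
    if disc < 0:
        raise InvalidGeometryError(
            f"thin-lens geometry needs fd >= 4f (fd={fd_mm} mm, f={f_mm} mm)"
        )
    return 0.5 * (fd_mm + math.sqrt(disc))


def project_length(
    true_length_mm: float,
    fd_mm: float,
    camera: CameraSpec,
    variant: ModelVariant = "simple",
) -> float:
    """Forward pinhole model: project a real-world length to sensor pixels.

    Returns the (sub-pixel, real-valued) image length of a fronto-parallel
    feature of ``true_length_mm`` photographed at focus distance ``fd_mm``.
    Strictly decreasing in ``fd_mm`` and strictly increasing in
    ``true_length_mm``.
    """
    if not true_length_mm > 0:
        raise InvalidGeometryError(f"true_length_mm must be > 0, got {true_length_mm}")
    f = camera.focal_length_mm
    if not fd_mm > f:
        raise InvalidGeometryError(
            f"fd_mm must exceed the focal length ({f} mm), got {fd_mm}"
        )
    y = camera.pixel_size_mm
    if variant == "simple":
        return f * true_length_mm / (fd_mm * y)
    if variant == "thin_lens":
        d = _thin_lens_object_distance(fd_mm, f)
        v = fd_mm - d
        return true_length_mm * (v / d) / y
    raise ConfigError(f"unknown model variant: {variant!r}")


def invert_projection(
    pixel_length: float,
    true_length_mm: float,
    camera: CameraSpec,
    variant: ModelVariant = "simple",
) -> float:
    """Inverse pinhole model: focus distance from a measured pixel length.

    This is the estimator core shared by the frontal and profile chains:
    ``simple`` returns ``f * L / (x * y)``; ``thin_lens`` solves the lens
    equation for the sensor-plane distance ``fd = f * (1 + m)**2 / m`` with
    magnification ``m = x * y / L``.
    """
    if not pixel_length > 0:
        raise InvalidGeometryError(f"pixel_length must be > 0, got {pixel_length}")
    if not true_length_mm > 0:
        raise InvalidGeometryError(f"true_length_mm must be > 0, got {true_length_mm}")
    f = camera.focal_length_mm
    y = camera.pixel_size_mm
    if variant == "simple":
        return f * true_length_mm / (pixel_length * y)
    if variant == "thin_lens":
        m = pixel_length * y / true_length_mm
        if m >= 1.0:
            raise InvalidGeometryError(
                f"magnification {m:.3g} >= 1: object would sit inside the focal length"
            )
        return f * (1.0 + m) ** 2 / m
    raise ConfigError(f"unknown model variant: {variant!r}")


def actual_focal_from_equivalent(f35_mm: float, sensor_diagonal_mm: float) -> float:
    """Convert a 35 mm-equivalent focal length to the actual focal length.

    Smartphone makers typically publish only the 35 mm-equivalent value; the
    actual focal length is ``f35 * diagonal / 43.2666`` where 43.2666 mm is
    the full-frame sensor diagonal.  Linear in both arguments.
    """
    if not f35_mm > 0 or not sensor_diagonal_mm > 0:
        raise ConfigError(
            f"f35_mm and sensor_diagonal_mm must be > 0, "
            f"got {f35_mm} and {sensor_diagonal_mm}"
        )
    return f35_mm * sensor_diagonal_mm / FULL_FRAME_DIAGONAL_MM


_EXIF_FOCAL_LENGTH = 0x920A
_EXIF_IFD_POINTER = 0x8769


def read_exif_focal_length(image_path: str | Path) -> Optional[float]:
    """Read the EXIF ``FocalLength`` tag (mm) from a JPEG, or ``None``.

    Only the actual focal length tag is trusted; ``FocalLengthIn35mmFilm`` is
    never silently converted because that needs a caller-supplied sensor
    diagonal (see :func:`actual_focal_from_equivalent`).
    """
    from PIL import Image, UnidentifiedImageError

    path = Path(image_path)
    try:
        with Image.open(path) as im:
            exif = im.getexif()
    except (OSError, UnidentifiedImageError) as exc:
        raise OSError(f"cannot read EXIF from {path.name}: {exc}") from exc
    value = exif.get(_EXIF_FOCAL_LENGTH)
    if value is None:
        # Real-world JPEGs nest FocalLength inside the Exif sub-IFD.
        value = exif.get_ifd(_EXIF_IFD_POINTER).get(_EXIF_FOCAL_LENGTH)
    if value is None:
        return None
    return float(value)
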