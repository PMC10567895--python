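"""Perspective-distortion tolerance for craniofacial superimposition.

An FD estimation error matters only insofar as it changes the perspective of
the rendered face.  Perspective is summarised here by the ratio of projected
scales of the nearest and farthest facial features contributing to
physiognomical face height, separated axially by a configurable depth extent
``delta``: at focus distance ``fd`` the near feature is magnified relative to
the far one by ``(fd + delta) / fd``, a ratio that tends to 1 as the camera
recedes.  The acceptance criterion used in superimposition work bounds the
change in physiognomical facial height at 1%.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigError, InvalidGeometryError


@dataclass(frozen=True)
class FaceDepthModel:
    """Axial depth extent (mm) between the near and far face-height features.

    No anthropometric standard fixes this value; fixtures use a nominal
    100 mm (roughly the nose-tip to tragus axial separation) and it must be
    supplied explicitly in configs.
    """

    depth_extent_mm: float

    def __post_init__(self) -> None:
        if not self.depth_extent_mm > 0:
            raise ConfigError("depth_extent_mm must be > 0")


def perspective_ratio(fd_mm: float, depth_model: FaceDepthModel) -> float:
    """Projected-scale ratio of the near vs far feature at distance ``fd_mm``."""
    if not fd_mm > 0:
        raise InvalidGeometryError(f"fd_mm must be > 0, got {fd_mm}")
    return (fd_mm + depth_model.depth_extent_mm) / fd_mm


def facial_height_change_pct(
    fd_true_mm: float, fd_est_mm: float, depth_model: FaceDepthModel
) -> float:
    """Percent change in physiognomical face height implied by an FD error.

    Zero iff the estimate equals the truth; approximately (not exactly)
    symmetric under swapping the two distances.
    """
    r_true = perspective_ratio(fd_true_mm, depth_model)
    r_est = perspective_ratio(fd_est_mm, depth_model)
    return 100.0 * abs(r_est / r_true - 1.0)


def within_tolerance(
    fd_true_mm: float,
    fd_est_mm: float,
    depth_model: FaceDepthModel,
    threshold_pct: float = 1.0,
) -> bool:
    """True iff the implied face-height change is within ``threshold_pct``.

    The comparison is inclusive (``<=``).
    """
    if not threshold_pct > 0:
        raise ConfigError("threshold_pct must be > 0")
    return facial_height_change_pct(fd_true_mm, fd_est_mm, depth_model) <= threshold_pct
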