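"""Anatomical coordinate frames for C1/C2 built from three sagittal-plane landmarks.

A vertebra's frame is defined by three ROI points placed in its sagittal
(symmetry) plane: an origin ``O`` and two points ``A``, ``B`` lying on the
in-plane reference axis.  The frame axes are

* ``X`` — the in-plane reference axis, unit vector from ``B`` toward ``A``
  (for C2 this is the craniocaudal axis along the ventral border of the
  vertebral foramen; for C1 the axis derived from the cranial border of the
  dorsal and ventral arches),
* ``Y`` — the unit normal of the plane through ``O``, ``A``, ``B``
  (mediolateral, perpendicular to the sagittal plane),
* ``Z`` — ``X × Y`` (ventrodorsal, completing a right-handed triad).

Implant vectors are re-expressed in this frame by a change of basis before
projected angles are computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DegenerateLandmarksError",
    "AnatomicalLandmarks",
    "AnatomicalFrame",
    "build_frame",
    "to_anatomical",
]

#: Minimum area (mm^2) of triangle O-A-B below which landmarks are rejected
#: as collinear; well under operator placement precision (~0.3 mm).
COLLINEARITY_AREA_TOL = 1e-6


class DegenerateLandmarksError(ValueError):
    """Raised when O, A, B are collinear or coincident and span no plane."""


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a 3D point, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("point coordinates must be finite")
    return a


@dataclass(frozen=True)
class AnatomicalLandmarks:
    """The O/A/B landmark triplet of one vertebra, in scanner millimetres.

    ``A`` must be placed cranial to ``B`` so that the X axis points
    cranially (the line fixes the axis, the ordering fixes its sense).
    """

    O: np.ndarray
    A: np.ndarray
    B: np.ndarray
    vertebra: str = "C2"

    def __post_init__(self):
        object.__setattr__(self, "O", _as_point(self.O))
        object.__setattr__(self, "A", _as_point(self.A))
        object.__setattr__(self, "B", _as_point(self.B))
        if self.vertebra not in ("C1", "C2"):
            raise ValueError(f"vertebra must be 'C1' or 'C2', got {self.vertebra!r}")


@dataclass(frozen=True)
class AnatomicalFrame:
    """Orthonormal right-handed frame (origin + X/Y/Z axes) of one vertebra."""

    origin: np.ndarray
    X_axis: np.ndarray
    Y_axis: np.ndarray
    Z_axis: np.ndarray
    vertebra: str = "C2"

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix whose *rows* are the X, Y, Z axes (world -> anatomical)."""
        return np.vstack([self.X_axis, self.Y_axis, self.Z_axis])


def build_frame(landmarks: AnatomicalLandmarks) -> AnatomicalFrame:
    """Construct the anatomical frame from an O/A/B landmark triplet.

    X is the unit vector from B to A; Y the unit normal of plane(O, A, B)
    oriented as ``(A - O) × (B - O)``; Z completes the right-handed triad.

    Raises
    ------
    DegenerateLandmarksError
        If the triangle O-A-B has area below ``COLLINEARITY_AREA_TOL``
        (collinear or coincident landmarks).
    """
    O, A, B = landmarks.O, landmarks.A, landmarks.B
    ab = A - B
    normal = np.cross(A - O, B - O)
    area = 0.5 * np.linalg.norm(normal)
    if area <= COLLINEARITY_AREA_TOL:
        raise DegenerateLandmarksError(
            f"landmarks O={O}, A={A}, B={B} are collinear or coincident "
            f"(triangle area {area:.3g} mm^2)"
        )
    x = ab / np.linalg.norm(ab)
    y = normal / np.linalg.norm(normal)
    z = np.cross(x, y)
    return AnatomicalFrame(origin=O.copy(), X_axis=x, Y_axis=y, Z_axis=z,
                           vertebra=landmarks.vertebra)


def to_anatomical(frame: AnatomicalFrame, start, end) -> np.ndarray:
    """Express the vector from ``start`` to ``end`` in anatomical coordinates.

    Returns the (craniocaudal, mediolateral, ventrodorsal) components,
    i.e. the dot products of ``end - start`` with the frame's X, Y, Z axes.
    Length is preserved (pure rotation, no scaling).  A zero vector is
    permitted and maps to zero.
    """
    d = _as_point(end) - _as_point(start)
    return frame.rotation @ d
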