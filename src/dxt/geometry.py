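"""Laboratory-frame geometry primitives and the beam, goniometer and scan models.

Conventions
-----------
The laboratory frame is right-handed, with its origin at the intersection of
the primary beam and the sample.  By default the beam propagates along
``(0, 0, 1)`` (source to sample) and the goniometer rotation axis is
``(+1, 0, 0)`` with a right-handed rotation sense; format classes override
these defaults when a beamline deviates from them.  Positions are in
millimetres, wavelengths in angstroms and all angles at public interfaces in
degrees (image headers store degrees; radians appear only transiently inside
the math).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

__all__ = [
    "GeometryError",
    "ScanRangeError",
    "ScanAppendError",
    "vec3",
    "unit",
    "is_unit",
    "rotation_about_axis",
    "Beam",
    "Goniometer",
    "Scan",
]

#: tolerance for "this vector is a unit vector"
UNIT_TOL = 1e-9


class GeometryError(ValueError):
    """A model violates a geometric invariant."""


class ScanRangeError(IndexError):
    """An image index lies outside a scan's image range."""


class ScanAppendError(GeometryError):
    """Two scans are not contiguous and cannot be appended."""


def vec3(x, y=None, z=None) -> np.ndarray:
    """Build a 3-vector as a float64 numpy array.

    Accepts either three scalars or a single length-3 sequence.
    """
    if y is None:
        v = np.asarray(x, dtype=float)
    else:
        v = np.array([x, y, z], dtype=float)
    if v.shape != (3,):
        raise GeometryError(f"expected a 3-vector, got shape {v.shape}")
    return v


def unit(v) -> np.ndarray:
    """Normalize ``v`` to unit length."""
    v = vec3(v)
    n = np.linalg.norm(v)
    if n == 0.0:
        raise GeometryError("cannot normalize the zero vector")
    return v / n


def is_unit(v, tol: float = UNIT_TOL) -> bool:
    return abs(np.linalg.norm(np.asarray(v, dtype=float)) - 1.0) <= tol


def rotation_about_axis(axis, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix for a right-handed rotation about ``axis``.

    Parameters
    ----------
    axis : array-like
        Unit rotation axis (checked to |1 - |axis|| <= 1e-9).
    angle_deg : float
        Rotation angle in degrees; positive angles are right-handed
        (counter-clockwise looking down the axis toward the origin).

    Returns
    -------
    (3, 3) ndarray
        Proper rotation matrix R with R @ v rotating column vectors.
    """
    axis = vec3(axis)
    if not is_unit(axis):
        raise GeometryError(f"rotation axis must be a unit vector, |axis|={np.linalg.norm(axis)}")
    theta = math.radians(angle_deg)
    c, s = math.cos(theta), math.sin(theta)
    x, y, z = axis
    K = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) + s * K + (1.0 - c) * (K @ K)


@dataclass
class Beam:
    """A monochromatic beam: unit propagation direction (source→sample) and
    wavelength in angstroms."""

    direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    wavelength: float = 1.0

    def __post_init__(self):
        self.direction = vec3(self.direction)
        if not is_unit(self.direction):
            raise GeometryError("beam direction must be a unit vector")
        self.wavelength = float(self.wavelength)
        if not self.wavelength > 0:
            raise GeometryError(f"wavelength must be positive, got {self.wavelength}")

    @property
    def s0(self) -> np.ndarray:
        """Incident wavevector s0 = direction / wavelength, in inverse angstroms."""
        return self.direction / self.wavelength

    def __eq__(self, other):
        if not isinstance(other, Beam):
            return NotImplemented
        return (
            np.allclose(self.direction, other.direction, rtol=0.0, atol=1e-9)
            and abs(self.wavelength - other.wavelength) <= 1e-9
        )


@dataclass
class Goniometer:
    """A single-axis rotation stage with right-handed sense about an
    arbitrary unit axis (not assumed orthogonal to the beam)."""

    rotation_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))

    def __post_init__(self):
        self.rotation_axis = vec3(self.rotation_axis)
        if not is_unit(self.rotation_axis):
            raise GeometryError("rotation axis must be a unit vector")

    def reversed(self) -> "Goniometer":
        """The same stage with the rotation sense flipped (left-handed axis)."""
        return Goniometer(-self.rotation_axis)

    def __eq__(self, other):
        if not isinstance(other, Goniometer):
            return NotImplemented
        return np.allclose(self.rotation_axis, other.rotation_axis, rtol=0.0, atol=1e-9)


@dataclass(frozen=True)
class Scan:
    """The mapping between image frames and rotation angle.

    ``image_range`` is 1-based inclusive ``(first, last)``; ``osc_start`` is
    the rotation angle at the start of the first image and ``osc_width`` the
    oscillation per image, both in degrees.  A still has ``osc_width == 0``.
    """

    image_range: Tuple[int, int] = (1, 1)
    osc_start: float = 0.0
    osc_width: float = 0.0

    def __post_init__(self):
        first, last = self.image_range
        object.__setattr__(self, "image_range", (int(first), int(last)))
        object.__setattr__(self, "osc_start", float(self.osc_start))
        object.__setattr__(self, "osc_width", float(self.osc_width))
        if self.image_range[1] < self.image_range[0]:
            raise GeometryError(f"image range {self.image_range} has last < first")
        if self.osc_width < 0:
            raise GeometryError("oscillation width must be >= 0")

    @property
    def n_images(self) -> int:
        return self.image_range[1] - self.image_range[0] + 1

    @property
    def is_still(self) -> bool:
        return self.osc_width == 0.0

    def angle_at(self, index: int, fraction: float = 0.0) -> float:
        """Rotation angle (degrees) at ``fraction`` through image ``index``.

        ``fraction = 0`` is the start of the image exposure, ``1`` the end.
        """
        first, last = self.image_range
        if not first <= index <= last:
            raise ScanRangeError(f"image {index} outside range {self.image_range}")
        return self.osc_start + (index - first + fraction) * self.osc_width

    def append(self, other: "Scan") -> "Scan":
        """Concatenate a contiguous following scan.

        ``other`` must start at the next image number, have the same
        oscillation width, and start at the angle where this scan ends
        (within 1e-3 x osc_width, absolute floor 1e-6 degrees, to absorb
        header rounding).  Raises :class:`ScanAppendError` otherwise;
        callers then start a new sweep.
        """
        if not isinstance(other, Scan):
            raise TypeError("can only append a Scan")
        if other.image_range[0] != self.image_range[1] + 1:
            raise ScanAppendError(
                f"image ranges {self.image_range} and {other.image_range} are not contiguous"
            )
        if abs(other.osc_width - self.osc_width) > 1e-9:
            raise ScanAppendError(
                f"oscillation widths differ: {self.osc_width} vs {other.osc_width}"
            )
        end_angle = self.osc_start + self.n_images * self.osc_width
        tol = max(1e-3 * self.osc_width, 1e-6)
        if abs(other.osc_start - end_angle) > tol:
            raise ScanAppendError(
                f"angular gap: expected start {end_angle}, got {other.osc_start}"
            )
        return Scan((self.image_range[0], other.image_range[1]), self.osc_start, self.osc_width)

    def __add__(self, other):
        return self.append(other)

    def slice(self, start: int, stop: int) -> "Scan":
        """Sub-scan over images ``start:stop`` (0-based offsets into this scan)."""
        first, last = self.image_range
        if not (0 <= start < stop <= self.n_images):
            raise ScanRangeError(f"slice [{start}, {stop}) invalid for {self.n_images} images")
        return Scan(
            (first + start, first + stop - 1),
            self.osc_start + start * self.osc_width,
            self.osc_width,
        )
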