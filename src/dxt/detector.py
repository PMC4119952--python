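"""Multi-panel detector model with per-panel d-matrix geometry.

A detector is a flat, ordered list of rectangular :class:`Panel` objects,
optionally organized under a tree of :class:`PanelGroup` frames (for
detectors whose panel groups move together, like quadrant-based pixel array
detectors).  Each panel carries a d-matrix

    d = [ f | s | o ]

whose columns are the unit fast axis f, unit slow axis s and the origin
vector o (the lab position of the outer corner of pixel (0, 0) on the front,
sample-facing sensor surface, in mm).  The d-matrix maps panel coordinates
(x_mm, y_mm, 1) to laboratory positions; its inverse projects a scattered
ray direction onto the panel plane without any trigonometry:

    v = d^-1 @ s_ray;   intersection at (v1/v3, v2/v3)   if v3 > 0.

A point on the virtual detector plane is a :class:`PlaneCoord`: the panel id
plus the (fast_mm, slow_mm) coordinate.  The fast coordinate always comes
first in pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, NamedTuple, Optional, Sequence, Tuple, Union

import numpy as np

from .geometry import GeometryError, is_unit, vec3
from .px_mm import PxMmStrategy, SimplePxMmStrategy

__all__ = [
    "Panel",
    "PanelGroup",
    "Detector",
    "PlaneCoord",
    "RayOutsidePlane",
    "SingularGeometryError",
]

#: d^-1 @ s third component below this means the ray never meets the panel front
V3_TOL = 1e-10


class RayOutsidePlane(GeometryError):
    """A ray is parallel to the panel plane or exits through the back."""


class SingularGeometryError(GeometryError):
    """The panel plane passes through the lab origin: d-matrix not invertible."""


class PlaneCoord(NamedTuple):
    """A virtual-detector-plane position: panel id + (fast, slow) mm."""

    panel_id: int
    xy: Tuple[float, float]


@dataclass
class Panel:
    """One rectangular sensor plane.

    ``origin`` is the lab-frame position (mm) of the outer corner of pixel
    (0, 0) on the front sensor surface; ``fast_axis`` and ``slow_axis`` are
    mutually orthogonal unit vectors along the pixel grid.  ``trusted_range``
    is carried as metadata and applied only by the imageset mask operation,
    never by geometry code.
    """

    name: str = "panel"
    fast_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    slow_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, -1.0, 0.0]))
    origin: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 100.0]))
    pixel_size: Tuple[float, float] = (0.1, 0.1)
    image_size: Tuple[int, int] = (1024, 1024)  # (n_fast, n_slow)
    trusted_range: Tuple[float, float] = (0.0, 65535.0)
    px_mm: PxMmStrategy = field(default_factory=SimplePxMmStrategy)

    def __post_init__(self):
        self.fast_axis = vec3(self.fast_axis)
        self.slow_axis = vec3(self.slow_axis)
        self.origin = vec3(self.origin)
        if not (is_unit(self.fast_axis) and is_unit(self.slow_axis)):
            raise GeometryError(f"panel {self.name!r}: fast/slow axes must be unit vectors")
        if abs(float(self.fast_axis @ self.slow_axis)) > 1e-7:
            # reject rather than re-orthogonalize: silent repair hides format bugs
            raise GeometryError(f"panel {self.name!r}: fast and slow axes not orthogonal")
        self.pixel_size = (float(self.pixel_size[0]), float(self.pixel_size[1]))
        if not (self.pixel_size[0] > 0 and self.pixel_size[1] > 0):
            raise GeometryError(f"panel {self.name!r}: pixel size must be positive")
        self.image_size = (int(self.image_size[0]), int(self.image_size[1]))
        if not (self.image_size[0] > 0 and self.image_size[1] > 0):
            raise GeometryError(f"panel {self.name!r}: image size must be positive")
        self.trusted_range = (float(self.trusted_range[0]), float(self.trusted_range[1]))

    # -- geometry ---------------------------------------------------------

    @property
    def normal(self) -> np.ndarray:
        """Unit panel normal, fast x slow."""
        return np.cross(self.fast_axis, self.slow_axis)

    @property
    def d_matrix(self) -> np.ndarray:
        """3x3 matrix with columns (fast_axis, slow_axis, origin)."""
        return np.column_stack([self.fast_axis, self.slow_axis, self.origin])

    @property
    def d_matrix_inv(self) -> np.ndarray:
        d = self.d_matrix
        if abs(np.linalg.det(d)) < 1e-12:
            raise SingularGeometryError(
                f"panel {self.name!r}: plane passes through the lab origin"
            )
        return np.linalg.inv(d)

    @property
    def limits_mm(self) -> Tuple[float, float]:
        """Panel extent (fast_mm, slow_mm)."""
        return (
            self.image_size[0] * self.pixel_size[0],
            self.image_size[1] * self.pixel_size[1],
        )

    def lab_coord(self, xy_mm) -> np.ndarray:
        """Lab position of a panel point: origin + x*fast + y*slow.

        Extrapolation beyond the panel limits is allowed; inside-ness is a
        separate check.
        """
        x, y = float(xy_mm[0]), float(xy_mm[1])
        return self.origin + x * self.fast_axis + y * self.slow_axis

    def is_coord_valid_mm(self, xy_mm) -> bool:
        lx, ly = self.limits_mm
        return 0.0 <= xy_mm[0] <= lx and 0.0 <= xy_mm[1] <= ly

    def ray_intersect(self, s) -> Tuple[Tuple[float, float], bool]:
        """Project a scattered ray direction onto the panel plane.

        Returns ``((fast_mm, slow_mm), inside)``; purely matrix algebra, no
        trigonometry.  Raises :class:`RayOutsidePlane` if the ray is
        parallel to the plane or points into the back hemisphere
        (``v3 <= 1e-10`` in d^-1 s units).
        """
        s = vec3(s)
        if not is_unit(s, tol=1e-6):
            raise GeometryError("ray direction must be a unit vector")
        v = self.d_matrix_inv @ s
        if v[2] <= V3_TOL:
            raise RayOutsidePlane(f"ray does not meet the front of panel {self.name!r}")
        xy = (v[0] / v[2], v[1] / v[2])
        return xy, self.is_coord_valid_mm(xy)

    def get_beam_centre(self, beam) -> Tuple[float, float]:
        """Intersection of the direct beam with this panel, in mm."""
        xy, _ = self.ray_intersect(beam.direction)
        return xy

    # -- pixel mapping ----------------------------------------------------

    def mm_to_px(self, xy_mm) -> Tuple[float, float]:
        return self.px_mm.mm_to_px(self, xy_mm)

    def px_to_mm(self, xy_px) -> Tuple[float, float]:
        return self.px_mm.px_to_mm(self, xy_px)

    def __eq__(self, other):
        if not isinstance(other, Panel):
            return NotImplemented
        return (
            np.allclose(self.fast_axis, other.fast_axis, rtol=0.0, atol=1e-9)
            and np.allclose(self.slow_axis, other.slow_axis, rtol=0.0, atol=1e-9)
            and np.allclose(self.origin, other.origin, rtol=0.0, atol=1e-9)
            and self.pixel_size == other.pixel_size
            and self.image_size == other.image_size
            and self.trusted_range == other.trusted_range
            and self.px_mm == other.px_mm
        )


@dataclass
class PanelGroup:
    """A node in the detector hierarchy.

    The local ``fast_axis``/``slow_axis``/``origin`` define the frame that
    maps child coordinates into the parent frame; children are ordered and
    may be panels or further groups.
    """

    name: str = "group"
    fast_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    slow_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    children: List[Union["PanelGroup", Panel]] = field(default_factory=list)

    def __post_init__(self):
        self.fast_axis = vec3(self.fast_axis)
        self.slow_axis = vec3(self.slow_axis)
        self.origin = vec3(self.origin)
        if not (is_unit(self.fast_axis) and is_unit(self.slow_axis)):
            raise GeometryError(f"group {self.name!r}: frame axes must be unit vectors")
        if abs(float(self.fast_axis @ self.slow_axis)) > 1e-7:
            raise GeometryError(f"group {self.name!r}: frame axes not orthogonal")

    @property
    def rotation(self) -> np.ndarray:
        """3x3 frame rotation with columns (fast, slow, fast x slow)."""
        return np.column_stack(
            [self.fast_axis, self.slow_axis, np.cross(self.fast_axis, self.slow_axis)]
        )

    def is_identity(self) -> bool:
        return np.allclose(self.rotation, np.eye(3), atol=1e-12) and np.allclose(
            self.origin, 0.0, atol=1e-12
        )


def _compose(group: PanelGroup, child_fast, child_slow, child_origin):
    R = group.rotation
    return R @ child_fast, R @ child_slow, R @ child_origin + group.origin


def flatten_hierarchy(root: PanelGroup) -> "Detector":
    """Resolve a panel-group tree into a flat Detector.

    Each leaf panel's global frame is the composition of its ancestors'
    frames applied to its local frame; the flat panel order is depth-first.
    Shared nodes / cycles raise :class:`GeometryError`.
    """
    panels: List[Panel] = []
    seen = set()

    def walk(node, R, t):
        if id(node) in seen:
            raise GeometryError("detector hierarchy is not a tree (shared node or cycle)")
        seen.add(id(node))
        if isinstance(node, Panel):
            p = Panel(
                name=node.name,
                fast_axis=R @ node.fast_axis,
                slow_axis=R @ node.slow_axis,
                origin=R @ node.origin + t,
                pixel_size=node.pixel_size,
                image_size=node.image_size,
                trusted_range=node.trusted_range,
                px_mm=node.px_mm,
            )
            panels.append(p)
        elif isinstance(node, PanelGroup):
            Rn = R @ node.rotation
            tn = R @ node.origin + t
            for child in node.children:
                walk(child, Rn, tn)
        else:
            raise TypeError(f"unexpected hierarchy node {type(node).__name__}")

    Rr, tr = root.rotation, root.origin
    for child in root.children:
        walk(child, Rr, tr)
    det = Detector(panels)
    det.root = root
    return det


class Detector:
    """An ordered container of panels with stable integer ids.

    The flat list order equals the depth-first leaf order of the hierarchy
    when the detector was built from one (see :func:`flatten_hierarchy`);
    ``root`` then references the original tree.
    """

    def __init__(self, panels: Sequence[Panel]):
        panels = list(panels)
        if not panels:
            raise GeometryError("a detector needs at least one panel")
        self.panels: List[Panel] = panels
        self.root: Optional[PanelGroup] = None

    def __len__(self):
        return len(self.panels)

    def __iter__(self):
        return iter(self.panels)

    def __getitem__(self, i) -> Panel:
        return self.panels[i]

    def ray_intersect(self, s) -> Optional[PlaneCoord]:
        """Virtual-plane coordinate where the ray ``s`` strikes the detector.

        Among panels whose intersection falls inside the panel limits the
        lowest panel id wins (deterministic tie-break for overlapping
        panels).  Returns ``None`` when no panel is hit — a ray missing the
        detector is a normal outcome, not an error.
        """
        for pid, panel in enumerate(self.panels):
            try:
                xy, inside = panel.ray_intersect(s)
            except RayOutsidePlane:
                continue
            if inside:
                return PlaneCoord(pid, xy)
        return None

    def beam_centre(self, beam) -> Optional[PlaneCoord]:
        """Direct-beam intersection with the detector (virtual-plane mm)."""
        return self.ray_intersect(beam.direction)

    def __eq__(self, other):
        if not isinstance(other, Detector):
            return NotImplemented
        return len(self) == len(other) and all(a == b for a, b in zip(self, other))
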