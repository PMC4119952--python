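"""Millimetre-to-pixel strategies for the virtual detector plane.

A position on the virtual detector plane is a millimetre coordinate on the
front (sample-facing) sensor surface.  The mapping from that coordinate to
the hardware pixel that records the photon is detector specific, so it is
delegated to an interchangeable strategy object attached to each panel:

* :class:`SimplePxMmStrategy` — pure division by the pixel size; correct for
  thin sensors.
* :class:`ParallaxCorrectedPxMmStrategy` — for thick sensors, where an
  obliquely incident photon penetrates some depth before conversion and is
  recorded displaced from its entry point along the in-plane component of
  the ray.

Parallax model
--------------
The ray from the laboratory origin (the sample) to the front-surface point
enters the sensor at angle theta to the panel normal and traverses a path of
length ``T = t0 / cos(theta)`` through a slab of thickness ``t0``.  With
Beer--Lambert absorption at linear coefficient ``mu`` the mean conversion
depth measured along the ray is

    t_bar = 1/mu - T * exp(-mu T) / (1 - exp(-mu T))

and the recorded position is the entry point displaced by ``t_bar`` times the
in-plane (tangential) component of the unit ray.  As ``t0 -> 0`` or
``mu -> inf`` the offset vanishes and the mapping reduces to the simple one.
The inverse mapping has no closed form and is solved by fixed-point
iteration (tolerance 1e-8 mm, at most 20 iterations).

Pixel coordinates are continuous; integer pixel indices are the floor of the
continuous coordinate, so pixel centres sit at half-integers.
"""

from __future__ import annotations

import math
from typing import Tuple

import numpy as np

__all__ = [
    "PxMmStrategy",
    "SimplePxMmStrategy",
    "ParallaxCorrectedPxMmStrategy",
    "ConvergenceError",
    "mean_conversion_depth",
]


class ConvergenceError(RuntimeError):
    """The parallax inverse fixed point failed to converge."""


def mean_conversion_depth(mu: float, path_length: float) -> float:
    """Mean depth along the ray at which a photon converts in the sensor.

    ``mu`` is the linear attenuation coefficient (mm^-1) and ``path_length``
    the in-sensor path ``T`` (mm).  This is the first moment of the
    truncated exponential depth distribution on [0, T].
    """
    a = mu * path_length
    if a <= 0.0:
        return 0.5 * path_length  # uniform-absorption limit
    # 1 - exp(-a) via expm1 keeps precision for small a
    denom = -math.expm1(-a)
    return 1.0 / mu - path_length * math.exp(-a) / denom


class PxMmStrategy:
    """Base strategy: the abstract mm <-> px mapping for one panel."""

    kind = "abstract"

    def mm_to_px(self, panel, xy_mm: Tuple[float, float]) -> Tuple[float, float]:
        raise NotImplementedError

    def px_to_mm(self, panel, xy_px: Tuple[float, float]) -> Tuple[float, float]:
        raise NotImplementedError

    def __eq__(self, other):
        return type(self) is type(other) and self.__dict__ == other.__dict__

    def __repr__(self):
        return f"{type(self).__name__}()"


class SimplePxMmStrategy(PxMmStrategy):
    """Uniform pixel grid: mm and px differ only by the pixel size."""

    kind = "simple"

    def mm_to_px(self, panel, xy_mm):
        fx, fy = panel.pixel_size
        return (xy_mm[0] / fx, xy_mm[1] / fy)

    def px_to_mm(self, panel, xy_px):
        fx, fy = panel.pixel_size
        return (xy_px[0] * fx, xy_px[1] * fy)


class ParallaxCorrectedPxMmStrategy(PxMmStrategy):
    """Parallax correction for thick sensors.

    Parameters
    ----------
    mu : float
        Linear attenuation coefficient of the sensor material at the beam
        energy, in mm^-1 (e.g. ~2.3 mm^-1 for 320 um silicon at 12.4 keV).
    t0 : float
        Sensor thickness in mm.
    """

    kind = "parallax"

    def __init__(self, mu: float, t0: float):
        if not mu > 0:
            raise ValueError(f"mu must be positive, got {mu}")
        if not t0 > 0:
            raise ValueError(f"t0 must be positive, got {t0}")
        self.mu = float(mu)
        self.t0 = float(t0)

    def __repr__(self):
        return f"ParallaxCorrectedPxMmStrategy(mu={self.mu}, t0={self.t0})"

    def _offset(self, panel, xy_mm) -> np.ndarray:
        """In-plane displacement (mm, fast/slow components) of the recorded
        position relative to the front-surface entry point ``xy_mm``."""
        p = panel.lab_coord(xy_mm)
        norm = np.linalg.norm(p)
        if norm == 0.0:
            return np.zeros(2)
        s = p / norm  # unit ray from sample to entry point
        n = panel.normal
        cos_t = abs(float(s @ n))
        if cos_t < 1e-12:
            return np.zeros(2)  # grazing: entry point is on the panel edge anyway
        path = self.t0 / cos_t
        depth = mean_conversion_depth(self.mu, path)
        tangent = s - (s @ n) * n  # in-plane component of the ray
        return depth * np.array([tangent @ panel.fast_axis, tangent @ panel.slow_axis])

    def mm_to_px(self, panel, xy_mm):
        recorded = np.asarray(xy_mm, dtype=float) + self._offset(panel, xy_mm)
        fx, fy = panel.pixel_size
        return (recorded[0] / fx, recorded[1] / fy)

    def px_to_mm(self, panel, xy_px, tol: float = 1e-8, max_iter: int = 20):
        fx, fy = panel.pixel_size
        recorded = np.array([xy_px[0] * fx, xy_px[1] * fy])
        # fixed point: entry = recorded - offset(entry)
        entry = recorded.copy()
        for _ in range(max_iter):
            new = recorded - self._offset(panel, entry)
            if np.max(np.abs(new - entry)) <= tol:
                return (new[0], new[1])
            entry = new
        raise ConvergenceError(
            f"parallax inverse did not converge within {max_iter} iterations at {tuple(xy_px)}"
        )
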