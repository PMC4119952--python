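"""Synthetic diffraction image generation for testing and demonstration.

The generator writes fully valid SMV sweeps and HDF5 stacks whose geometry
is encoded by the package's own models: each requested spot is a unit ray
direction that is projected onto the detector with the d-matrix machinery
and rendered as a two-dimensional Gaussian blob (sigma 1.5 px, truncated at
4 sigma) on a flat background, optionally with Poisson counting noise.
This closes the loop between generation and readback: importing the files
and computing the intensity-weighted centroid of each blob must recover
the generating ray.

No crystallographic physics is simulated — there is no lattice and no
Ewald-sphere construction; spots are arbitrary rays.  The default
parameters describe a compact but realistic rotation experiment: a single
400x400 panel of 0.1 mm pixels 150 mm from the sample, a 0.9795 angstrom
beam through the panel centre, and 0.5 degree oscillations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import h5py
import numpy as np

from .detector import Detector, Panel
from .geometry import Beam, rotation_about_axis, unit

__all__ = ["FixtureSpec", "write_smv_sweep", "write_hdf5_stack", "weighted_centroid", "random_spots"]

SPOT_SIGMA_PX = 1.5  # Gaussian blob width
SPOT_TRUNCATE_SIGMA = 4.0


@dataclass
class FixtureSpec:
    """Everything needed to generate a deterministic synthetic sweep.

    ``spots`` is a list of ``(unit_ray, total_counts)`` pairs; the same
    spots are rendered on every image (the geometry is static).  The seed
    fixes the output bytes exactly.
    """

    distance: float = 150.0          # mm, sample to panel along the beam
    beam_centre: Tuple[float, float] = (20.0, 20.0)  # mm (fast, slow)
    pixel_size: float = 0.1          # mm
    image_size: Tuple[int, int] = (400, 400)  # (n_fast, n_slow)
    wavelength: float = 0.9795       # angstrom
    osc_start: float = 0.0           # degrees
    osc_width: float = 0.5           # degrees / image; 0 marks stills
    n_images: int = 3
    serial_number: str = "210"
    two_theta: Optional[float] = None  # degrees; adds TWOTHETA to headers
    spots: List[Tuple[np.ndarray, float]] = field(default_factory=list)
    background: float = 40.0         # counts / pixel
    poisson_noise: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("distance", "pixel_size", "wavelength", "background"):
            if getattr(self, name) < 0 or (name in ("distance", "pixel_size") and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        self.spots = [(unit(s), float(i)) for s, i in self.spots]

    # -- the models the headers will describe -----------------------------

    def panel(self) -> Panel:
        fast = np.array([1.0, 0.0, 0.0])
        slow = np.array([0.0, -1.0, 0.0])
        origin = np.array([-self.beam_centre[0], self.beam_centre[1], self.distance])
        if self.two_theta is not None:
            # same convention as the 2-theta format class: the header beam
            # centre is recorded at the 2-theta offset, the whole frame is
            # rotated by -2theta about lab x
            R = rotation_about_axis((1.0, 0.0, 0.0), -self.two_theta)
            fast, slow, origin = R @ fast, R @ slow, R @ origin
        return Panel(
            name="ADSC",
            fast_axis=fast,
            slow_axis=slow,
            origin=origin,
            pixel_size=(self.pixel_size, self.pixel_size),
            image_size=self.image_size,
        )

    def detector(self) -> Detector:
        return Detector([self.panel()])

    def beam(self) -> Beam:
        return Beam(direction=(0.0, 0.0, 1.0), wavelength=self.wavelength)

    def spot_pixel_positions(self) -> List[Tuple[np.ndarray, float, Tuple[float, float]]]:
        """(ray, counts, continuous px position) for every spot that hits
        the detector; rays that miss are reported by the writers and
        skipped."""
        det = self.detector()
        out = []
        for ray, counts in self.spots:
            hit = det.ray_intersect(ray)
            if hit is None:
                continue
            panel = det[hit.panel_id]
            out.append((ray, counts, panel.mm_to_px(hit.xy)))
        return out


def _render_images(spec: FixtureSpec) -> Tuple[np.ndarray, List[np.ndarray]]:
    """Deterministic pixel stack (n_images, n_slow, n_fast) as uint16, plus
    the list of rays that missed the detector."""
    n_fast, n_slow = spec.image_size
    hits = spec.spot_pixel_positions()
    hit_rays = {id(r) for r, _, _ in hits}
    missed = [r for r, _ in spec.spots if id(r) not in hit_rays]

    base = np.full((n_slow, n_fast), float(spec.background))
    half = int(np.ceil(SPOT_TRUNCATE_SIGMA * SPOT_SIGMA_PX))
    for _, counts, (px, py) in hits:
        # blob window in integer pixels; pixel centres at half-integers
        x0, x1 = int(np.floor(px)) - half, int(np.floor(px)) + half + 1
        y0, y1 = int(np.floor(py)) - half, int(np.floor(py)) + half + 1
        x0c, x1c = max(x0, 0), min(x1, n_fast)
        y0c, y1c = max(y0, 0), min(y1, n_slow)
        if x0c >= x1c or y0c >= y1c:
            continue
        xs = np.arange(x0c, x1c) + 0.5
        ys = np.arange(y0c, y1c) + 0.5
        gx = np.exp(-0.5 * ((xs - px) / SPOT_SIGMA_PX) ** 2)
        gy = np.exp(-0.5 * ((ys - py) / SPOT_SIGMA_PX) ** 2)
        kernel = np.outer(gy, gx)
        kernel *= counts / (2.0 * np.pi * SPOT_SIGMA_PX**2)
        base[y0c:y1c, x0c:x1c] += kernel

    rng = np.random.default_rng(spec.seed)
    images = np.empty((spec.n_images, n_slow, n_fast), dtype="<u2")
    for i in range(spec.n_images):
        if spec.poisson_noise:
            frame = rng.poisson(base)
        else:
            frame = np.round(base).astype(np.int64)
        images[i] = np.clip(frame, 0, 65535).astype("<u2")
    return images, missed


def _smv_header(spec: FixtureSpec, image_index: int, header_bytes: int = 512) -> bytes:
    lines = [
        "{",
        f"HEADER_BYTES={header_bytes};",
        "DIM=2;",
        "BYTE_ORDER=little_endian;",
        "TYPE=unsigned_short;",
        f"SIZE1={spec.image_size[1]};",
        f"SIZE2={spec.image_size[0]};",
        f"PIXEL_SIZE={spec.pixel_size!r};",
        f"DISTANCE={spec.distance!r};",
        f"WAVELENGTH={spec.wavelength!r};",
        f"BEAM_CENTER_X={spec.beam_centre[0]!r};",
        f"BEAM_CENTER_Y={spec.beam_centre[1]!r};",
        f"OSC_START={spec.osc_start + image_index * spec.osc_width!r};",
        f"OSC_RANGE={spec.osc_width!r};",
        f"DETECTOR_SN={spec.serial_number};",
    ]
    if spec.two_theta is not None:
        lines.append(f"TWOTHETA={spec.two_theta!r};")
    lines.append("}")
    text = "\n".join(lines) + "\n"
    raw = text.encode("ascii")
    if len(raw) > header_bytes:
        raise ValueError("header does not fit in HEADER_BYTES")
    return raw + b" " * (header_bytes - len(raw))


def write_smv_sweep(
    spec: FixtureSpec, directory, prefix: str = "image", start_number: int = 1
) -> List[Path]:
    """Write the sweep as one SMV file per image, named ``prefix_0001.img``
    onward.  Returns the written paths; rays that miss the detector are
    skipped (and available via the rendering report)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    images, _missed = _render_images(spec)
    paths = []
    for i in range(spec.n_images):
        path = directory / f"{prefix}_{start_number + i:04d}.img"
        with open(path, "wb") as fh:
            fh.write(_smv_header(spec, i))
            fh.write(images[i].tobytes())
        paths.append(path)
    return paths


def write_hdf5_stack(spec: FixtureSpec, path) -> Path:
    """Write the same sweep as a single HDF5 container.

    The pixel arrays are byte-identical to those of :func:`write_smv_sweep`
    for an identical spec (both writers share one renderer)."""
    path = Path(path)
    images, _missed = _render_images(spec)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=images, dtype="<u2")
        geo = f.create_group("geometry")
        geo["SIZE1"] = spec.image_size[1]
        geo["SIZE2"] = spec.image_size[0]
        geo["PIXEL_SIZE"] = spec.pixel_size
        geo["DISTANCE"] = spec.distance
        geo["WAVELENGTH"] = spec.wavelength
        geo["BEAM_CENTER_X"] = spec.beam_centre[0]
        geo["BEAM_CENTER_Y"] = spec.beam_centre[1]
        scan = f.create_group("scan")
        scan["osc_start"] = spec.osc_start
        scan["osc_range"] = spec.osc_width
    return path


def random_spots(
    spec: FixtureSpec,
    n: int,
    rng,
    counts: float = 2000.0,
    margin_px: float = 20.0,
    min_separation_px: float = 16.0,
) -> List[Tuple[np.ndarray, float]]:
    """Draw ``n`` spot rays hitting the detector uniformly in pixel space.

    Spots keep ``margin_px`` clear of the panel edges and at least
    ``min_separation_px`` apart (rejection sampling), so every rendered
    blob is fully resolvable — overlapping blobs would make their
    centroids meaningless."""
    panel = spec.panel()
    n_fast, n_slow = spec.image_size
    placed: List[Tuple[float, float]] = []
    spots = []
    attempts = 0
    while len(spots) < n:
        attempts += 1
        if attempts > 1000 * n:
            raise ValueError(f"cannot place {n} spots {min_separation_px} px apart")
        px = rng.uniform(margin_px, n_fast - margin_px)
        py = rng.uniform(margin_px, n_slow - margin_px)
        if any((px - qx) ** 2 + (py - qy) ** 2 < min_separation_px**2 for qx, qy in placed):
            continue
        placed.append((px, py))
        lab = panel.lab_coord(panel.px_to_mm((px, py)))
        spots.append((unit(lab), counts))
    return spots


def weighted_centroid(
    image: np.ndarray, near_px: Tuple[float, float], radius: int = 6, background: float = 0.0
) -> Tuple[float, float]:
    """Background-subtracted intensity-weighted centroid (continuous px) of
    the blob in a square window around ``near_px``.

    Negative residuals after background subtraction are kept: clipping them
    would bias the centroid toward the window centre.  The default window
    half-width matches the blob truncation radius (4 sigma = 6 px)."""
    n_slow, n_fast = image.shape
    px, py = near_px
    x0, x1 = max(int(px) - radius, 0), min(int(px) + radius + 1, n_fast)
    y0, y1 = max(int(py) - radius, 0), min(int(py) + radius + 1, n_slow)
    window = image[y0:y1, x0:x1].astype(float) - background
    total = window.sum()
    if total <= 0:
        raise ValueError(f"no intensity near {near_px}")
    xs = np.arange(x0, x1) + 0.5
    ys = np.arange(y0, y1) + 0.5
    cx = float((window.sum(axis=0) * xs).sum() / total)
    cy = float((window.sum(axis=1) * ys).sum() / total)
    return (cx, cy)
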