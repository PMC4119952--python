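"""Multi-image HDF5 container format.

Container schema: ``/data`` — the image stack, shape
``(n_images, n_slow, n_fast)``, unsigned 16-bit; ``/geometry/*`` — scalar
datasets mirroring the SMV header keys (``DISTANCE``, ``WAVELENGTH``,
``PIXEL_SIZE``, ``BEAM_CENTER_X``, ``BEAM_CENTER_Y``, ``SIZE1``,
``SIZE2``); ``/scan/osc_start`` and ``/scan/osc_range`` in degrees.  One
set of models describes the whole stack, whose scan covers images
``1..n_images``.
"""

from __future__ import annotations

import h5py
import numpy as np

from ..geometry import Scan
from .base import Format, MalformedContainerError
from .smv import smv_build_models

__all__ = ["FormatHDF5Stack", "hdf5_stack_models"]

_GEOMETRY_KEYS = (
    "SIZE1",
    "SIZE2",
    "PIXEL_SIZE",
    "DISTANCE",
    "WAVELENGTH",
    "BEAM_CENTER_X",
    "BEAM_CENTER_Y",
)


def _header_from_container(f: h5py.File) -> dict:
    if "data" not in f:
        raise MalformedContainerError("container lacks /data")
    if "geometry" not in f:
        raise MalformedContainerError("container lacks /geometry")
    if "scan" not in f:
        raise MalformedContainerError("container lacks /scan")
    header = {}
    geo = f["geometry"]
    for key in _GEOMETRY_KEYS:
        if key not in geo:
            raise MalformedContainerError(f"container lacks /geometry/{key}")
        header[key] = str(geo[key][()])
    scan = f["scan"]
    for key in ("osc_start", "osc_range"):
        if key not in scan:
            raise MalformedContainerError(f"container lacks /scan/{key}")
    header["OSC_START"] = str(scan["osc_start"][()])
    header["OSC_RANGE"] = str(scan["osc_range"][()])
    return header


def hdf5_stack_models(path):
    """Models and image count for an HDF5 stack.

    Returns ``((beam, detector, goniometer, scan), n_images)``; raises
    :class:`MalformedContainerError` when required datasets are missing.
    """
    with h5py.File(path, "r") as f:
        header = _header_from_container(f)
        n_images = int(f["data"].shape[0])
    beam, detector, goniometer, scan = smv_build_models(header, image_index=1)
    scan = Scan((1, n_images), scan.osc_start, scan.osc_width)
    return (beam, detector, goniometer, scan), n_images


class FormatHDF5Stack(Format):
    """HDF5 image-stack container with the schema above."""

    format_name = "HDF5Stack"
    parent_format = Format
    multi_image = True

    @classmethod
    def understands(cls, path) -> bool:
        try:
            return h5py.is_hdf5(path)
        except OSError:
            return False

    def __init__(self, path):
        super().__init__(path)
        (self._beam, self._detector, self._goniometer, self._scan), self._n = (
            hdf5_stack_models(path)
        )

    def n_images(self) -> int:
        return self._n

    def get_beam(self):
        return self._beam

    def get_detector(self):
        return self._detector

    def get_goniometer(self):
        return self._goniometer

    def get_scan(self):
        return self._scan

    def get_raw_data(self, index: int = 0) -> np.ndarray:
        if not 0 <= index < self._n:
            raise IndexError(f"image {index} outside stack of {self._n}")
        with h5py.File(self.path, "r") as f:
            return np.asarray(f["data"][index])
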