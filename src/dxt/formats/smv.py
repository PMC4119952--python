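"""The SMV text-header image family (ADSC dialect) and two beamline variants.

SMV dialect handled here: an ASCII header ``{\\n KEY=VALUE;\\n ... }\\n``
padded with whitespace to ``HEADER_BYTES`` bytes, followed by unsigned
16-bit little-endian pixels with the fast index contiguous.  ``SIZE1`` is
the slow (row) count and ``SIZE2`` the fast (column) count.  The beam
centre keys are interpreted in millimetres, X along the fast axis and Y
along the slow axis (one dialect; pixel-unit variants would be further
subclasses).

Standard model mapping for a plain ADSC header:

* detector — single panel, fast ``(1, 0, 0)``, slow ``(0, -1, 0)``, origin
  ``(-BEAM_CENTER_X, +BEAM_CENTER_Y, DISTANCE)``, so the direct beam along
  ``(0, 0, 1)`` strikes the panel at the header beam centre;
* beam — direction ``(0, 0, 1)``, header wavelength;
* goniometer — axis ``(+1, 0, 0)``, right-handed;
* scan — one image at the filename's sequence number, ``OSC_START`` /
  ``OSC_RANGE`` degrees (``OSC_RANGE = 0`` marks a still).

Two concrete beamline idiosyncrasies are modelled as subclasses gated on
the detector serial number (the gate values here are synthetic fixture
constants, configurable per class): a reversed (left-handed) rotation axis,
and a detector carried on a 2-theta arm where the header beam centre is
recorded at the 2-theta offset so the whole panel frame must be rotated by
``-2θ`` about the lab x axis.
"""

from __future__ import annotations

import re
from typing import Dict, Tuple

import numpy as np

from ..detector import Detector, Panel
from ..geometry import Beam, Goniometer, Scan, rotation_about_axis
from .base import Format, MalformedHeaderError, MissingMetadataError

__all__ = [
    "smv_read_header",
    "smv_build_models",
    "FormatSMV",
    "FormatSMVADSC",
    "FormatSMVADSCReversedPhi",
    "FormatSMVADSCTwoTheta",
]

#: header keys a plain ADSC image must provide to build models
REQUIRED_KEYS = (
    "SIZE1",
    "SIZE2",
    "PIXEL_SIZE",
    "DISTANCE",
    "WAVELENGTH",
    "BEAM_CENTER_X",
    "BEAM_CENTER_Y",
    "OSC_START",
    "OSC_RANGE",
)

_KV = re.compile(rb"^\s*([A-Za-z0-9_]+)\s*=\s*(.*?)\s*;\s*$")


def smv_read_header(data: bytes) -> Dict[str, str]:
    """Parse an SMV text header into an upper-cased key -> text-value map.

    ``data`` is the raw start of the file (at least ``HEADER_BYTES`` bytes).
    Raises :class:`MalformedHeaderError` on a missing opening brace, a
    missing ``HEADER_BYTES`` key, or a file shorter than ``HEADER_BYTES``.
    """
    if not data.startswith(b"{"):
        raise MalformedHeaderError("SMV header must begin with '{'")
    # HEADER_BYTES must appear in the leading lines to bound the header
    probe = data[: min(len(data), 4096)]
    m = re.search(rb"HEADER_BYTES\s*=\s*(\d+)\s*;", probe)
    if m is None:
        raise MalformedHeaderError("SMV header lacks HEADER_BYTES")
    header_bytes = int(m.group(1))
    if len(data) < header_bytes:
        raise MalformedHeaderError(
            f"file truncated: {len(data)} bytes < HEADER_BYTES={header_bytes}"
        )
    header: Dict[str, str] = {}
    for line in data[:header_bytes].split(b"\n"):
        kv = _KV.match(line)
        if kv:
            header[kv.group(1).decode("ascii").upper()] = kv.group(2).decode("ascii")
    return header


def smv_build_models(header: Dict[str, str], image_index: int = 1):
    """Build (beam, detector, goniometer, scan) from a parsed ADSC header.

    ``image_index`` is the 1-based position of this image in its filename
    sequence; the single-image scan covers exactly that frame.  Raises
    :class:`MissingMetadataError` naming the first absent required key.
    """
    for key in REQUIRED_KEYS:
        if key not in header:
            raise MissingMetadataError(f"SMV header missing required key {key}")
    n_slow = int(header["SIZE1"])
    n_fast = int(header["SIZE2"])
    pixel = float(header["PIXEL_SIZE"])
    distance = float(header["DISTANCE"])
    bcx = float(header["BEAM_CENTER_X"])
    bcy = float(header["BEAM_CENTER_Y"])

    beam = Beam(direction=(0.0, 0.0, 1.0), wavelength=float(header["WAVELENGTH"]))
    panel = Panel(
        name="ADSC",
        fast_axis=(1.0, 0.0, 0.0),
        slow_axis=(0.0, -1.0, 0.0),
        origin=(-bcx, bcy, distance),
        pixel_size=(pixel, pixel),
        image_size=(n_fast, n_slow),
        trusted_range=(0.0, 65535.0),
    )
    detector = Detector([panel])
    goniometer = Goniometer(rotation_axis=(1.0, 0.0, 0.0))
    scan = Scan(
        image_range=(image_index, image_index),
        osc_start=float(header["OSC_START"]),
        osc_width=float(header["OSC_RANGE"]),
    )
    return beam, detector, goniometer, scan


def _sequence_number(path) -> int:
    """Trailing run of digits in the file stem, or 1 when absent."""
    from pathlib import Path

    m = re.search(r"(\d+)(?!.*\d)", Path(path).stem)
    return int(m.group(1)) if m else 1


class FormatSMV(Format):
    """Any file with a well-formed SMV text header."""

    format_name = "SMV"
    parent_format = Format

    @staticmethod
    def read_header(path) -> Dict[str, str]:
        with open(path, "rb") as fh:
            probe = fh.read(4096)
            m = re.search(rb"HEADER_BYTES\s*=\s*(\d+)\s*;", probe)
            if m is None:
                return smv_read_header(probe)  # raises with a clear message
            need = int(m.group(1))
            if need > len(probe):
                probe += fh.read(need - len(probe))
        return smv_read_header(probe)

    @classmethod
    def understands(cls, path) -> bool:
        try:
            cls.read_header(path)
        except (OSError, MalformedHeaderError):
            return False
        return True

    def __init__(self, path):
        super().__init__(path)
        self.header = self.read_header(path)

    def get_raw_data(self, index: int = 0) -> np.ndarray:
        if index != 0:
            raise IndexError("single-image file")
        header_bytes = int(self.header["HEADER_BYTES"])
        n_slow = int(self.header["SIZE1"])
        n_fast = int(self.header["SIZE2"])
        with open(self.path, "rb") as fh:
            fh.seek(header_bytes)
            data = np.frombuffer(fh.read(2 * n_fast * n_slow), dtype="<u2")
        return data.reshape(n_slow, n_fast)


class FormatSMVADSC(FormatSMV):
    """Plain ADSC detector on a conventional beamline."""

    format_name = "SMVADSC"
    parent_format = FormatSMV

    @classmethod
    def understands(cls, path) -> bool:
        try:
            header = cls.read_header(path)
        except (OSError, MalformedHeaderError):
            return False
        return all(key in header for key in REQUIRED_KEYS)

    def _models(self):
        return smv_build_models(self.header, image_index=_sequence_number(self.path))

    def get_beam(self):
        return self._models()[0]

    def get_detector(self):
        return self._models()[1]

    def get_goniometer(self):
        return self._models()[2]

    def get_scan(self):
        return self._models()[3]


class FormatSMVADSCReversedPhi(FormatSMVADSC):
    """ADSC beamline with a left-handed (reversed) rotation axis.

    Gated on the detector serial number; only the goniometer axis sign
    differs from the parent's models.
    """

    format_name = "SMVADSCReversedPhi"
    parent_format = FormatSMVADSC
    gated_serial_numbers = ("915",)

    @classmethod
    def understands(cls, path) -> bool:
        if not FormatSMVADSC.understands(path):
            return False
        header = cls.read_header(path)
        return header.get("DETECTOR_SN") in cls.gated_serial_numbers

    def get_goniometer(self):
        return super().get_goniometer().reversed()


class FormatSMVADSCTwoTheta(FormatSMVADSC):
    """ADSC detector carried on a 2-theta arm.

    The header beam centre is recorded at the 2-theta offset, so the whole
    panel frame (fast, slow and origin) built by the parent is rotated by
    ``-TWOTHETA`` degrees about the lab ``(1, 0, 0)`` axis through the lab
    origin.  All other models are the parent's.  Gated on the detector
    serial number.
    """

    format_name = "SMVADSCTwoTheta"
    parent_format = FormatSMVADSC
    gated_serial_numbers = ("926",)

    @classmethod
    def understands(cls, path) -> bool:
        if not FormatSMVADSC.understands(path):
            return False
        header = cls.read_header(path)
        return header.get("DETECTOR_SN") in cls.gated_serial_numbers

    def get_detector(self):
        if "TWOTHETA" not in self.header:
            raise MissingMetadataError("SMV header missing required key TWOTHETA")
        two_theta = float(self.header["TWOTHETA"])
        detector = super().get_detector()
        R = rotation_about_axis((1.0, 0.0, 0.0), -two_theta)
        panels = [
            Panel(
                name=p.name,
                fast_axis=R @ p.fast_axis,
                slow_axis=R @ p.slow_axis,
                origin=R @ p.origin,
                pixel_size=p.pixel_size,
                image_size=p.image_size,
                trusted_range=p.trusted_range,
                px_mm=p.px_mm,
            )
            for p in detector
        ]
        return Detector(panels)
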