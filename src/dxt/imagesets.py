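"""ImageSet / ImageSweep access layer and the DataBlock factory.

Input images are grouped top-down: files are resolved to format classes,
one :class:`DataBlock` is made per format class, and within a block images
are partitioned into sweeps (rotation series whose beam, detector and
goniometer models compare equal and whose single-image scans chain
contiguously under filename-number order) and sets (stills, and rotation
images that cannot be merged).  Grouping is canonical: the result is
independent of the order the paths were supplied in.

Both set and sweep are lightweight views over a shared reader object
(flyweight): subsets keep a reference to the very same reader, and a
sweep's beam/detector/goniometer are one shared object visible through
every subset.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Type

import numpy as np

from .formats import FormatRegistry, UnknownFormatError, global_registry
from .formats.base import Format
from .geometry import Beam, Goniometer, Scan, ScanAppendError

__all__ = [
    "MultiFileReader",
    "SingleFileReader",
    "ImageSet",
    "ImageSweep",
    "DataBlock",
    "datablocks_from_files",
    "filename_template",
]


def filename_template(path) -> Tuple[str, int]:
    """Split a filename into (template, sequence number).

    The template is the name with its last run of digits replaced by ``#``
    placeholders; files sharing a template belong to one candidate sequence
    ordered by the number.  A name with no digits gets number 1.
    """
    path = Path(path)
    m = re.search(r"(\d+)(?!.*\d)", path.stem)
    if m is None:
        return str(path), 1
    start, end = m.span(1)
    stem = path.stem
    template = stem[:start] + "#" * (end - start) + stem[end:] + path.suffix
    return str(path.with_name(template)), int(m.group(1))


class MultiFileReader:
    """Reader over a list of one-image-per-file paths sharing a format class."""

    kind = "multi_file"

    def __init__(self, format_class: Type[Format], paths: Sequence):
        if not paths:
            raise ValueError("a reader needs at least one path")
        self.format_class = format_class
        self.paths = [Path(p) for p in paths]
        self._instances: Dict[int, Format] = {}

    def __len__(self):
        return len(self.paths)

    def _instance(self, i: int) -> Format:
        if i not in self._instances:
            self._instances[i] = self.format_class(self.paths[i])
        return self._instances[i]

    def read(self, i: int) -> np.ndarray:
        return self._instance(i).get_raw_data(0)

    def models(self, i: int) -> dict:
        return self._instance(i).get_models()

    def path(self, i: int) -> Path:
        return self.paths[i]


class SingleFileReader:
    """Reader over one multi-image container file."""

    kind = "single_file"

    def __init__(self, format_class: Type[Format], path):
        self.format_class = format_class
        self.paths = [Path(path)]
        self._instance = format_class(path)

    def __len__(self):
        return self._instance.n_images()

    def read(self, i: int) -> np.ndarray:
        return self._instance.get_raw_data(i)

    def models(self, i: int) -> dict:
        return self._instance.get_models()

    def path(self, i: int) -> Path:
        return self.paths[0]


class ImageSet:
    """An ordered subset of a reader's images with per-image beam/detector.

    Used where consecutive images have no geometric relationship (stills).
    """

    def __init__(self, reader, indices: Sequence[int], beams=None, detectors=None):
        indices = list(indices)
        if not indices:
            raise ValueError("an image set needs at least one image")
        if any(b >= a for a, b in zip(indices[1:], indices)):
            raise ValueError("indices must be strictly increasing")
        self.reader = reader
        self.indices = indices
        self.beams = list(beams) if beams is not None else [None] * len(indices)
        self.detectors = list(detectors) if detectors is not None else [None] * len(indices)

    def __len__(self):
        return len(self.indices)

    def get_beam(self, i: int = 0) -> Beam:
        if self.beams[i] is None:
            self.beams[i] = self.reader.models(self.indices[i])["beam"]
        return self.beams[i]

    def get_detector(self, i: int = 0):
        if self.detectors[i] is None:
            self.detectors[i] = self.reader.models(self.indices[i])["detector"]
        return self.detectors[i]

    def get_raw_data(self, i: int) -> np.ndarray:
        if not 0 <= i < len(self):
            raise IndexError(f"image {i} outside set of {len(self)}")
        return self.reader.read(self.indices[i])

    def get_mask(self, i: int) -> np.ndarray:
        """Trusted-range mask: True where the pixel value is usable."""
        data = self.get_raw_data(i)
        lo, hi = self.get_detector(i)[0].trusted_range
        return (data >= lo) & (data <= hi)

    def paths(self) -> List[Path]:
        return [self.reader.path(i) for i in self.indices]

    def subset(self, start: int, stop: int) -> "ImageSet":
        """A view over images ``start:stop`` sharing this reader."""
        if not 0 <= start < stop <= len(self):
            raise IndexError(f"slice [{start}, {stop}) invalid for {len(self)} images")
        return ImageSet(
            self.reader,
            self.indices[start:stop],
            self.beams[start:stop],
            self.detectors[start:stop],
        )

    def __getitem__(self, key):
        if isinstance(key, slice):
            start, stop, step = key.indices(len(self))
            if step != 1:
                raise IndexError("only contiguous slices are supported")
            return self.subset(start, stop)
        return self.get_raw_data(key)


class ImageSweep(ImageSet):
    """A rotation series: one shared beam, detector, goniometer and a single
    contiguous scan whose length equals the image count."""

    def __init__(self, reader, indices, beam: Beam, detector, goniometer: Goniometer, scan: Scan):
        super().__init__(reader, indices)
        if scan.n_images != len(indices):
            raise ValueError(
                f"scan covers {scan.n_images} images but sweep has {len(indices)}"
            )
        self.beam = beam
        self.detector = detector
        self.goniometer = goniometer
        self.scan = scan

    # shared-model accessors: every image sees the same objects
    def get_beam(self, i: int = 0) -> Beam:
        return self.beam

    def get_detector(self, i: int = 0):
        return self.detector

    def get_goniometer(self) -> Goniometer:
        return self.goniometer

    def get_scan(self) -> Scan:
        return self.scan

    def subset(self, start: int, stop: int) -> "ImageSweep":
        if not 0 <= start < stop <= len(self):
            raise IndexError(f"slice [{start}, {stop}) invalid for {len(self)} images")
        return ImageSweep(
            self.reader,
            self.indices[start:stop],
            self.beam,
            self.detector,
            self.goniometer,
            self.scan.slice(start, stop),
        )


class DataBlock:
    """All input images interpreted by one format class, grouped into
    sweeps and sets."""

    def __init__(self, format_name: str, imagesets: Sequence[ImageSet]):
        self.format_name = format_name
        self.imagesets = list(imagesets)

    def sweeps(self) -> List[ImageSweep]:
        return [s for s in self.imagesets if isinstance(s, ImageSweep)]

    def sets(self) -> List[ImageSet]:
        return [s for s in self.imagesets if not isinstance(s, ImageSweep)]

    def paths(self) -> List[Path]:
        out: List[Path] = []
        for s in self.imagesets:
            out.extend(s.paths())
        return out


def _models_equal(a: dict, b: dict) -> bool:
    """Beam/detector/goniometer equality for sweep grouping (1e-9 on
    vectors, exact on integer fields; the model __eq__ methods implement
    this tolerance)."""
    return (
        a["beam"] == b["beam"]
        and a["detector"] == b["detector"]
        and a["goniometer"] == b["goniometer"]
    )


def _group_single_file(format_class, path) -> List[ImageSet]:
    reader = SingleFileReader(format_class, path)
    models = reader.models(0)
    indices = list(range(len(reader)))
    scan: Scan = models["scan"]
    if scan is not None and not scan.is_still and models["goniometer"] is not None:
        return [
            ImageSweep(
                reader, indices, models["beam"], models["detector"], models["goniometer"], scan
            )
        ]
    return [ImageSet(reader, indices)]


def _group_multi_file(format_class, paths: List[Path]) -> List[ImageSet]:
    """Partition a canonically ordered file list into sweeps and sets."""
    reader = MultiFileReader(format_class, paths)
    models = [reader.models(i) for i in range(len(reader))]
    templates = [filename_template(p)[0] for p in paths]

    out: List[ImageSet] = []
    still_indices: List[int] = []
    run: List[int] = []  # reader indices of the sweep being grown
    run_scan: Optional[Scan] = None  # accumulated scan of the run

    def close_run():
        nonlocal run_scan
        if run:
            first = models[run[0]]
            out.append(
                ImageSweep(
                    reader, list(run), first["beam"], first["detector"],
                    first["goniometer"], run_scan,
                )
            )
            run.clear()
            run_scan = None

    for i in range(len(reader)):
        scan = models[i]["scan"]
        if scan is None or scan.is_still:
            still_indices.append(i)  # stills are never merged into sweeps
            continue
        if run:
            prev = run[-1]
            extended = None
            if templates[i] == templates[prev] and _models_equal(models[prev], models[i]):
                try:
                    # a gap in image numbers or angles splits the sweep
                    extended = run_scan.append(scan)
                except ScanAppendError:
                    extended = None
            if extended is None:
                close_run()
                run_scan = scan
            else:
                run_scan = extended
        else:
            run_scan = scan
        run.append(i)
    close_run()
    if still_indices:
        out.append(ImageSet(reader, still_indices))
    return out


def datablocks_from_files(
    paths: Sequence,
    registry: Optional[FormatRegistry] = None,
    unhandled: Optional[list] = None,
) -> List[DataBlock]:
    """Group image files into data blocks.

    Files are resolved through the format registry; files no format
    understands (or that error while reading) are appended to ``unhandled``
    when a list is given, and are never a global failure.  One block is
    produced per format class, each containing the sweeps and sets built
    from its files; the output does not depend on the input path order.
    """
    registry = registry if registry is not None else global_registry
    resolved: Dict[str, Tuple[Type[Format], List[Path]]] = {}
    for p in paths:
        p = Path(p)
        try:
            fmt = registry.find_format_class(p)
        except (UnknownFormatError, OSError) as exc:
            if unhandled is not None:
                unhandled.append((p, str(exc)))
            continue
        resolved.setdefault(fmt.format_name, (fmt, []))[1].append(p)

    blocks: List[DataBlock] = []
    for name in sorted(resolved):
        fmt, fpaths = resolved[name]
        # canonical order: template, then sequence number, then full name
        fpaths = sorted(set(fpaths), key=lambda p: (*filename_template(p), str(p)))
        groups: List[ImageSet] = []
        if fmt.multi_image:
            for p in fpaths:
                try:
                    groups.extend(_group_single_file(fmt, p))
                except Exception as exc:
                    if unhandled is not None:
                        unhandled.append((p, str(exc)))
        else:
            groups.extend(_group_multi_file(fmt, fpaths))
        if groups:
            blocks.append(DataBlock(name, groups))
    return blocks
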