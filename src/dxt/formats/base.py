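"""Format plugin base class and the errors the plugin layer raises."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Type

import numpy as np


class FormatError(Exception):
    """Base class for format-layer errors."""


class UnknownFormatError(FormatError):
    """No registered format class understands the file."""


class MalformedHeaderError(FormatError):
    """The file header does not follow the dialect it claims."""


class MissingMetadataError(FormatError):
    """A header key required to build the models is absent."""


class MalformedContainerError(FormatError):
    """A multi-image container is missing required datasets."""


class DuplicateFormatError(FormatError):
    """A format class with this name is already registered."""


class OrphanFormatError(FormatError):
    """The parent of a format class is not registered."""


class Format:
    """Root of the format class tree.

    A format class interprets one image file dialect: it decides cheaply
    whether a file is in its dialect (:meth:`understands`, header-only by
    contract — interrogation runs over many files and must never read pixel
    data) and, once instantiated on a path, builds the standardized beam,
    detector, goniometer and scan models and reads the image data.

    Subclasses only specialize: ``understands(f)`` true implies
    ``parent.understands(f)`` true.  The root class understands any
    readable, non-empty file but builds no models; it anchors the tree and
    is never returned by the registry lookup.
    """

    #: registry display name; defaults to the class name
    format_name: str = "Format"
    #: parent class in the specialization tree; None marks the root
    parent_format: Optional[Type["Format"]] = None
    #: True when one file holds a stack of images (container formats)
    multi_image: bool = False

    @classmethod
    def understands(cls, path) -> bool:
        try:
            with open(path, "rb") as fh:
                return len(fh.read(1)) == 1
        except OSError:
            return False

    def __init__(self, path):
        self.path = Path(path)

    # -- model builders (overridden by concrete formats) -------------------

    def get_beam(self):
        raise NotImplementedError

    def get_detector(self):
        raise NotImplementedError

    def get_goniometer(self):
        raise NotImplementedError

    def get_scan(self):
        raise NotImplementedError

    def get_models(self) -> dict:
        """All four models as a dict (beam, detector, goniometer, scan)."""
        return {
            "beam": self.get_beam(),
            "detector": self.get_detector(),
            "goniometer": self.get_goniometer(),
            "scan": self.get_scan(),
        }

    def n_images(self) -> int:
        return 1

    def get_raw_data(self, index: int = 0) -> np.ndarray:
        raise NotImplementedError
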