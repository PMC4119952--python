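"""Format plugin system: base class, registry, and the built-in formats.

``default_registry()`` returns a fresh registry with the built-in formats
(SMV family and the HDF5 stack container) registered; ``global_registry``
is the shared instance most callers use.  Custom formats can be registered
directly or auto-loaded from a plugin directory at startup.
"""

from .base import (
    DuplicateFormatError,
    Format,
    FormatError,
    MalformedContainerError,
    MalformedHeaderError,
    MissingMetadataError,
    OrphanFormatError,
    UnknownFormatError,
)
from .hdf5 import FormatHDF5Stack, hdf5_stack_models
from .registry import FormatRegistry
from .smv import (
    FormatSMV,
    FormatSMVADSC,
    FormatSMVADSCReversedPhi,
    FormatSMVADSCTwoTheta,
    smv_build_models,
    smv_read_header,
)

__all__ = [
    "Format",
    "FormatRegistry",
    "FormatError",
    "UnknownFormatError",
    "MalformedHeaderError",
    "MissingMetadataError",
    "MalformedContainerError",
    "DuplicateFormatError",
    "OrphanFormatError",
    "FormatSMV",
    "FormatSMVADSC",
    "FormatSMVADSCReversedPhi",
    "FormatSMVADSCTwoTheta",
    "FormatHDF5Stack",
    "smv_read_header",
    "smv_build_models",
    "hdf5_stack_models",
    "default_registry",
    "global_registry",
]

_BUILTINS = (
    FormatSMV,
    FormatSMVADSC,
    FormatSMVADSCReversedPhi,
    FormatSMVADSCTwoTheta,
    FormatHDF5Stack,
)


def default_registry() -> FormatRegistry:
    """A new registry with all built-in format classes registered."""
    registry = FormatRegistry()
    for fmt in _BUILTINS:
        registry.register(fmt)
    return registry


#: shared registry used when no explicit registry is passed
global_registry = default_registry()
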