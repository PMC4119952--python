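"""Lossless JSON round trip for models and datablocks.

The document schema (this package's own dialect, versioned as ``"1"``) is a
single JSON object discriminated by a top-level ``kind`` key:

* ``kind: "models"`` — beam / detector / goniometer / scan sub-documents;
* ``kind: "datablock"`` — format class name plus the sweep/set structure,
  with image paths stored relative to the document's own location (pixel
  data is never embedded, only metadata).

Numbers are written at full ``repr`` precision, keys in deterministic
sorted order, so ``to_json(from_json(to_json(x))) == to_json(x)`` as text.
Unknown keys encountered on read are preserved and re-emitted on write.
All invariants (unit vectors, axis orthogonality, positive sizes) are
re-validated at load and violations rejected with the offending field
named.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Dict, List, Optional

from .detector import Detector, Panel, PanelGroup, flatten_hierarchy
from .geometry import Beam, GeometryError, Goniometer, Scan
from .imagesets import (
    DataBlock,
    ImageSet,
    ImageSweep,
    MultiFileReader,
    SingleFileReader,
)
from .px_mm import ParallaxCorrectedPxMmStrategy, PxMmStrategy, SimplePxMmStrategy

__all__ = [
    "SCHEMA_VERSION",
    "ParseError",
    "ValidationError",
    "models_to_json",
    "models_from_json",
    "datablock_to_json",
    "datablock_from_json",
]

SCHEMA_VERSION = "1"


class ParseError(ValueError):
    """The document is not well-formed JSON or not a known document kind."""


class ValidationError(ValueError):
    """A loaded model violates an invariant; the message names the field."""


def _dump(doc: dict) -> str:
    return json.dumps(doc, sort_keys=True, indent=1)


def _known(doc: dict, keys, extra_store: dict):
    """Split off unknown keys so they survive the round trip."""
    for k, v in doc.items():
        if k not in keys:
            extra_store[k] = v


def _merge_extra(base: dict, extra: Optional[dict]) -> dict:
    if extra:
        out = dict(extra)
        out.update(base)
        return out
    return base


# -- per-model converters --------------------------------------------------

def beam_to_dict(beam: Beam) -> dict:
    return _merge_extra(
        {"direction": list(beam.direction), "wavelength": beam.wavelength},
        getattr(beam, "_extra", None),
    )


def beam_from_dict(doc: dict) -> Beam:
    try:
        beam = Beam(direction=doc["direction"], wavelength=doc["wavelength"])
    except KeyError as exc:
        raise ValidationError(f"beam document missing field {exc}") from exc
    except GeometryError as exc:
        raise ValidationError(f"beam: {exc}") from exc
    extra: dict = {}
    _known(doc, {"direction", "wavelength"}, extra)
    if extra:
        beam._extra = extra
    return beam


def goniometer_to_dict(g: Goniometer) -> dict:
    return _merge_extra(
        {"rotation_axis": list(g.rotation_axis)}, getattr(g, "_extra", None)
    )


def goniometer_from_dict(doc: dict) -> Goniometer:
    try:
        g = Goniometer(rotation_axis=doc["rotation_axis"])
    except KeyError as exc:
        raise ValidationError(f"goniometer document missing field {exc}") from exc
    except GeometryError as exc:
        raise ValidationError(f"goniometer.rotation_axis: {exc}") from exc
    extra: dict = {}
    _known(doc, {"rotation_axis"}, extra)
    if extra:
        g._extra = extra
    return g


def scan_to_dict(scan: Scan) -> dict:
    return _merge_extra(
        {
            "image_range": list(scan.image_range),
            "osc_start": scan.osc_start,
            "osc_width": scan.osc_width,
        },
        getattr(scan, "_extra", None),
    )


def scan_from_dict(doc: dict) -> Scan:
    try:
        scan = Scan(
            image_range=tuple(doc["image_range"]),
            osc_start=doc["osc_start"],
            osc_width=doc["osc_width"],
        )
    except KeyError as exc:
        raise ValidationError(f"scan document missing field {exc}") from exc
    except GeometryError as exc:
        raise ValidationError(f"scan: {exc}") from exc
    extra: dict = {}
    _known(doc, {"image_range", "osc_start", "osc_width"}, extra)
    if extra:
        object.__setattr__(scan, "_extra", extra)
    return scan


def px_mm_to_dict(strategy: PxMmStrategy) -> dict:
    if isinstance(strategy, ParallaxCorrectedPxMmStrategy):
        return {"kind": "parallax", "mu": strategy.mu, "t0": strategy.t0}
    return {"kind": "simple"}


def px_mm_from_dict(doc: dict) -> PxMmStrategy:
    kind = doc.get("kind")
    if kind == "simple":
        return SimplePxMmStrategy()
    if kind == "parallax":
        try:
            return ParallaxCorrectedPxMmStrategy(mu=doc["mu"], t0=doc["t0"])
        except (KeyError, ValueError) as exc:
            raise ValidationError(f"px_mm: {exc}") from exc
    raise ValidationError(f"px_mm.kind: unknown strategy {kind!r}")


_PANEL_KEYS = {
    "name", "fast_axis", "slow_axis", "origin",
    "pixel_size", "image_size", "trusted_range", "px_mm",
}


def panel_to_dict(panel: Panel) -> dict:
    return _merge_extra(
        {
            "name": panel.name,
            "fast_axis": list(panel.fast_axis),
            "slow_axis": list(panel.slow_axis),
            "origin": list(panel.origin),
            "pixel_size": list(panel.pixel_size),
            "image_size": list(panel.image_size),
            "trusted_range": list(panel.trusted_range),
            "px_mm": px_mm_to_dict(panel.px_mm),
        },
        getattr(panel, "_extra", None),
    )


def panel_from_dict(doc: dict) -> Panel:
    try:
        panel = Panel(
            name=doc.get("name", "panel"),
            fast_axis=doc["fast_axis"],
            slow_axis=doc["slow_axis"],
            origin=doc["origin"],
            pixel_size=tuple(doc["pixel_size"]),
            image_size=tuple(doc["image_size"]),
            trusted_range=tuple(doc["trusted_range"]),
            px_mm=px_mm_from_dict(doc.get("px_mm", {"kind": "simple"})),
        )
    except KeyError as exc:
        raise ValidationError(f"panel document missing field {exc}") from exc
    except GeometryError as exc:
        raise ValidationError(f"panel: {exc}") from exc
    extra: dict = {}
    _known(doc, _PANEL_KEYS, extra)
    if extra:
        panel._extra = extra
    return panel


def _group_to_dict(group: PanelGroup) -> dict:
    return {
        "type": "group",
        "name": group.name,
        "fast_axis": list(group.fast_axis),
        "slow_axis": list(group.slow_axis),
        "origin": list(group.origin),
        "children": [
            _group_to_dict(c) if isinstance(c, PanelGroup) else dict(panel_to_dict(c), type="panel")
            for c in group.children
        ],
    }


def _group_from_dict(doc: dict):
    if doc.get("type") == "panel":
        return panel_from_dict({k: v for k, v in doc.items() if k != "type"})
    try:
        return PanelGroup(
            name=doc.get("name", "group"),
            fast_axis=doc["fast_axis"],
            slow_axis=doc["slow_axis"],
            origin=doc["origin"],
            children=[_group_from_dict(c) for c in doc["children"]],
        )
    except KeyError as exc:
        raise ValidationError(f"panel group missing field {exc}") from exc
    except GeometryError as exc:
        raise ValidationError(f"panel group: {exc}") from exc


def detector_to_dict(det: Detector) -> dict:
    doc: dict = {"panels": [panel_to_dict(p) for p in det]}
    if det.root is not None:
        doc["hierarchy"] = _group_to_dict(det.root)
    return doc


def detector_from_dict(doc: dict) -> Detector:
    try:
        panels = [panel_from_dict(p) for p in doc["panels"]]
    except KeyError as exc:
        raise ValidationError(f"detector document missing field {exc}") from exc
    det = Detector(panels)
    if "hierarchy" in doc:
        node = _group_from_dict(doc["hierarchy"])
        if not isinstance(node, PanelGroup):
            raise ValidationError("detector.hierarchy: root must be a group")
        det.root = node
        flat = flatten_hierarchy(node)
        if flat != det:
            raise ValidationError(
                "detector.hierarchy: flattened hierarchy disagrees with the panel list"
            )
    return det


# -- documents -------------------------------------------------------------

_MODEL_DOC_KEYS = {"schema_version", "kind", "beam", "detector", "goniometer", "scan"}


def models_to_dict(models: Dict) -> dict:
    """Document dict for a model set.

    ``models`` maps any subset of beam/detector/goniometer/scan to model
    objects; an ``extra`` entry holds preserved unknown document keys.
    """
    doc: dict = dict(models.get("extra", {}))
    doc["schema_version"] = SCHEMA_VERSION
    doc["kind"] = "models"
    if models.get("beam") is not None:
        doc["beam"] = beam_to_dict(models["beam"])
    if models.get("detector") is not None:
        doc["detector"] = detector_to_dict(models["detector"])
    if models.get("goniometer") is not None:
        doc["goniometer"] = goniometer_to_dict(models["goniometer"])
    if models.get("scan") is not None:
        doc["scan"] = scan_to_dict(models["scan"])
    return doc


def models_to_json(models: Dict) -> str:
    return _dump(models_to_dict(models))


def models_from_dict(doc: dict) -> Dict:
    if doc.get("kind") != "models":
        raise ParseError(f"expected a models document, got kind {doc.get('kind')!r}")
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ParseError(f"unsupported schema_version {doc.get('schema_version')!r}")
    models: Dict = {
        "beam": beam_from_dict(doc["beam"]) if "beam" in doc else None,
        "detector": detector_from_dict(doc["detector"]) if "detector" in doc else None,
        "goniometer": goniometer_from_dict(doc["goniometer"]) if "goniometer" in doc else None,
        "scan": scan_from_dict(doc["scan"]) if "scan" in doc else None,
    }
    extra = {k: v for k, v in doc.items() if k not in _MODEL_DOC_KEYS}
    if extra:
        models["extra"] = extra
    return models


def models_from_json(text: str) -> Dict:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"malformed JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise ParseError("document root must be a JSON object")
    return models_from_dict(doc)


# -- datablocks ------------------------------------------------------------

def _relpaths(paths: List[Path], anchor: Optional[Path]) -> List[str]:
    if anchor is None:
        return [str(p) for p in paths]
    return [os.path.relpath(p, anchor) for p in paths]


def datablock_to_dict(block: DataBlock, anchor=None) -> dict:
    """Document dict for a datablock; image paths relative to ``anchor``."""
    anchor = Path(anchor) if anchor is not None else None
    groups = []
    for iset in block.imagesets:
        entry: dict = {
            "paths": _relpaths(iset.paths(), anchor),
            "single_file": iset.reader.kind == "single_file",
            "indices": list(iset.indices),
        }
        if isinstance(iset, ImageSweep):
            entry["type"] = "sweep"
            entry["beam"] = beam_to_dict(iset.beam)
            entry["detector"] = detector_to_dict(iset.detector)
            entry["goniometer"] = goniometer_to_dict(iset.goniometer)
            entry["scan"] = scan_to_dict(iset.scan)
        else:
            entry["type"] = "set"
            entry["beam"] = [beam_to_dict(iset.get_beam(i)) for i in range(len(iset))]
            entry["detector"] = [
                detector_to_dict(iset.get_detector(i)) for i in range(len(iset))
            ]
        groups.append(entry)
    return {
        "schema_version": SCHEMA_VERSION,
        "kind": "datablock",
        "format": block.format_name,
        "imagesets": groups,
    }


def datablock_to_json(block: DataBlock, anchor=None) -> str:
    return _dump(datablock_to_dict(block, anchor))


def datablock_from_dict(doc: dict, anchor=None, registry=None) -> DataBlock:
    """Rebuild a datablock from its document.

    Relative image paths are resolved against ``anchor`` (the document's
    own directory when loading from a file).  Readers are reconstructed
    through the format registry; the stored models are used as-is rather
    than re-derived from headers.
    """
    from .formats import global_registry

    if doc.get("kind") != "datablock":
        raise ParseError(f"expected a datablock document, got kind {doc.get('kind')!r}")
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ParseError(f"unsupported schema_version {doc.get('schema_version')!r}")
    registry = registry if registry is not None else global_registry
    try:
        fmt = registry.get(doc["format"])
    except KeyError as exc:
        raise ValidationError(f"unknown format class {doc['format']!r}") from exc
    anchor = Path(anchor) if anchor is not None else Path(".")

    imagesets: List[ImageSet] = []
    for entry in doc["imagesets"]:
        paths = [anchor / p for p in entry["paths"]]
        if entry.get("single_file"):
            reader = SingleFileReader(fmt, paths[0])
        else:
            reader = MultiFileReader(fmt, paths)
            entry = dict(entry, indices=list(range(len(paths))))
        if entry["type"] == "sweep":
            imagesets.append(
                ImageSweep(
                    reader,
                    entry["indices"],
                    beam_from_dict(entry["beam"]),
                    detector_from_dict(entry["detector"]),
                    goniometer_from_dict(entry["goniometer"]),
                    scan_from_dict(entry["scan"]),
                )
            )
        else:
            beams = [beam_from_dict(b) for b in entry["beam"]]
            detectors = [detector_from_dict(d) for d in entry["detector"]]
            imagesets.append(ImageSet(reader, entry["indices"], beams, detectors))
    return DataBlock(doc["format"], imagesets)


def datablock_from_json(text: str, anchor=None, registry=None) -> DataBlock:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"malformed JSON: {exc}") from exc
    return datablock_from_dict(doc, anchor=anchor, registry=registry)
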