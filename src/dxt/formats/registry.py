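"""Registry of format classes: a specialization tree with lookup.

The registry keeps the format classes in a tree rooted at the universal
:class:`~dxt.formats.base.Format`, with the most specialized formats
furthest from the root.  Lookup walks the tree depth first and returns the
deepest class whose whole ancestor chain understands the file; among
equally deep matches the first-registered class wins.

Custom format classes dropped as ``.py`` files into a designated plugin
directory are loaded and registered at startup (:meth:`FormatRegistry.load_plugin_dir`);
a file that fails to load is logged and skipped, never fatal.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Type

from .base import (
    DuplicateFormatError,
    Format,
    OrphanFormatError,
    UnknownFormatError,
)

logger = logging.getLogger(__name__)


class FormatRegistry:
    def __init__(self):
        self._classes: Dict[str, Type[Format]] = {Format.format_name: Format}
        self._children: Dict[str, List[Type[Format]]] = {Format.format_name: []}

    @property
    def root(self) -> Type[Format]:
        return Format

    def __contains__(self, name: str) -> bool:
        return name in self._classes

    def get(self, name: str) -> Type[Format]:
        return self._classes[name]

    def names(self) -> List[str]:
        return list(self._classes)

    def register(self, fmt: Type[Format]) -> Type[Format]:
        """Add a format class under its declared parent.

        Raises :class:`DuplicateFormatError` if the name is taken and
        :class:`OrphanFormatError` if the parent is not yet registered.
        Returns the class, so it can be used as a decorator.
        """
        name = fmt.format_name
        if name in self._classes:
            raise DuplicateFormatError(f"format {name!r} already registered")
        parent = fmt.parent_format
        if parent is None:
            raise OrphanFormatError(f"format {name!r} declares no parent")
        if parent.format_name not in self._classes or self._classes[parent.format_name] is not parent:
            raise OrphanFormatError(
                f"format {name!r} has unregistered parent {parent.format_name!r}"
            )
        self._classes[name] = fmt
        self._children[name] = []
        self._children[parent.format_name].append(fmt)
        return fmt

    def children(self, fmt: Type[Format]) -> List[Type[Format]]:
        return list(self._children[fmt.format_name])

    def find_format_class(self, path) -> Type[Format]:
        """Most specialized format class that understands ``path``.

        Raises :class:`UnknownFormatError` when nothing below the root
        understands the file (the universal root itself is an anchor, not a
        usable format).
        """
        if not Format.understands(path):
            raise UnknownFormatError(f"unreadable or empty file: {path}")

        def deepest(node: Type[Format], depth: int):
            best = (node, depth)
            for child in self._children[node.format_name]:
                try:
                    ok = child.understands(path)
                except Exception:  # a broken plugin must not break lookup
                    logger.warning("understands() failed for %s", child.format_name, exc_info=True)
                    ok = False
                if ok:
                    cand = deepest(child, depth + 1)
                    if cand[1] > best[1]:
                        best = cand
            return best

        found, depth = deepest(Format, 0)
        if depth == 0:
            raise UnknownFormatError(f"no registered format understands {path}")
        return found

    def load_plugin_dir(self, directory) -> List[Type[Format]]:
        """Load every ``*.py`` file in ``directory`` and register the Format
        subclasses it defines.

        Classes are registered parents-first within each file; load or
        registration errors are logged and skipped.
        """
        directory = Path(directory)
        loaded: List[Type[Format]] = []
        if not directory.is_dir():
            logger.warning("plugin directory %s does not exist", directory)
            return loaded
        for py in sorted(directory.glob("*.py")):
            try:
                namespace: dict = {"__name__": f"dxt_plugin_{py.stem}", "__file__": str(py)}
                exec(compile(py.read_text(), str(py), "exec"), namespace)
            except Exception:
                logger.warning("failed to load plugin %s", py, exc_info=True)
                continue
            classes = [
                obj
                for obj in namespace.values()
                if isinstance(obj, type)
                and issubclass(obj, Format)
                and obj is not Format
                and obj.format_name not in self
            ]
            # register parents before children
            remaining = classes
            while remaining:
                progressed = []
                for cls in remaining:
                    parent = cls.parent_format
                    if parent is not None and parent.format_name in self:
                        try:
                            self.register(cls)
                            loaded.append(cls)
                        except Exception:
                            logger.warning(
                                "failed to register plugin class %s", cls.format_name, exc_info=True
                            )
                    else:
                        progressed.append(cls)
                if len(progressed) == len(remaining):
                    for cls in progressed:
                        logger.warning("plugin class %s has no registered parent", cls.format_name)
                    break
                remaining = progressed
        return loaded
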