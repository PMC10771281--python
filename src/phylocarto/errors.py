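"""Exception hierarchy.

Every error raised by the library derives from :class:`PhylocartoError`, so
callers (and the CLI) can catch one type.  Parse errors carry a character
offset into the offending text where that is known.
"""


class PhylocartoError(Exception):
    """Base class for all library errors."""


class NexusFormatError(PhylocartoError):
    """The document is not a single-tree annotated NEXUS file.

    ``offset`` is the 0-based character position of the problem in the
    input text, when it can be located.
    """

    def __init__(self, message: str, offset: int | None = None):
        if offset is not None:
            message = f"{message} (at character offset {offset})"
        super().__init__(message)
        self.offset = offset


class MissingAnnotationError(PhylocartoError):
    """A node lacks a required annotation (e.g. location coordinates)."""

    def __init__(self, message: str, node: str | int | None = None):
        super().__init__(message)
        self.node = node


class ParameterError(PhylocartoError):
    """A user-supplied parameter is out of its valid range."""


class LookupError_(PhylocartoError):
    """A referenced node id / taxon / state label does not exist."""


class CoverageError(PhylocartoError):
    """A clustering or result set does not cover the node set it must."""

    def __init__(self, message: str, missing=()):
        super().__init__(message)
        self.missing = tuple(missing)


class DataError(PhylocartoError):
    """Trait data inconsistent with the tree (unknown labels, missing tips)."""


class OptimizationError(PhylocartoError):
    """Likelihood optimization failed (non-finite objective)."""
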