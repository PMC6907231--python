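"""Exception hierarchy.

Format errors carry a byte offset where that is meaningful (binary dialects,
malformed XML) so callers can point at the corrupt region of a file.
"""


class ChemScanError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(ChemScanError):
    """Input does not conform to the expected file format."""

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (at byte offset {offset})"
        super().__init__(message)


class NotCdxml(FormatError):
    pass


class NotCdx(FormatError):
    pass


class NotDocx(FormatError):
    pass


class NotDoc(FormatError):
    pass


class GeometryError(ChemScanError):
    """Degenerate geometry (zero-length arrow, empty object list)."""


class MoleculeError(ChemScanError):
    """A fragment could not be turned into a sanitizable molecule."""

    def __init__(self, message: str, fragment_id: int | None = None):
        self.fragment_id = fragment_id
        if fragment_id is not None:
            message = f"{message} (fragment {fragment_id})"
        super().__init__(message)


class CyclicSchemeError(ChemScanError):
    """The arrow adjacency graph of a scheme contains a cycle."""
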