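"""Exception hierarchy for the motif-search pipeline."""


class StrucmotifError(Exception):
    """Base class for all package-specific errors."""


class ParseError(StrucmotifError):
    """A structure file could not be parsed; the message names the offending record."""


class EmptyStructureError(StrucmotifError):
    """A parsed file contained no usable polymer residue."""


class UnknownAssemblyError(StrucmotifError):
    """The requested biological assembly is not defined in the file."""

    def __init__(self, requested: str, available: list[str]):
        self.requested = requested
        self.available = available
        super().__init__(
            f"assembly {requested!r} not found; available: {available or ['(none)']}"
        )


class SelectorError(StrucmotifError):
    """A residue selector did not resolve to a residue."""


class DegenerateGeometryError(StrucmotifError):
    """Geometry is degenerate (collinear backbone, zero-length representative vector...)."""


class OutOfRangeError(StrucmotifError):
    """A pair geometry falls outside the indexable descriptor range."""


class InvalidKeyError(StrucmotifError):
    """A packed integer does not decode to a valid descriptor key."""


class IndexIntegrityError(StrucmotifError):
    """An on-disk index file is corrupt or inconsistent; the message names the file."""


class DuplicateStructureError(StrucmotifError):
    """A structure id is already present in the index."""


class MissingResidueError(StrucmotifError):
    """A requested residue is absent from the coordinate store."""


class MotifTooExtendedError(StrucmotifError):
    """The admissible-pair graph of a query motif is disconnected at the distance cutoff."""


class QueryError(StrucmotifError):
    """A motif query definition is invalid."""
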