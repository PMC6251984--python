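"""Exception hierarchy shared across the package.

Two broad families: :class:`InputFormatError` for problems in external
files (malformed GFF3/Newick/CIGAR/FASTA), and :class:`ModelError` for
structurally invalid biological objects (frame violations, overlapping
exons, unknown leaves).  The CLI maps these onto distinct exit codes.
"""


class FamvizError(Exception):
    """Base class for all package-specific errors."""


class InputFormatError(FamvizError):
    """An external file or text blob violates its format."""


class MalformedRecordError(InputFormatError):
    """A single record (e.g. one GFF3 line) is syntactically invalid."""


class LinkageError(InputFormatError):
    """A Parent/ID reference points at a feature that does not exist."""


class NewickParseError(InputFormatError):
    """Newick/NHX text could not be parsed."""

    def __init__(self, message: str, offset: int | None = None):
        if offset is not None:
            message = f"{message} (at character {offset})"
        super().__init__(message)
        self.offset = offset


class CigarError(InputFormatError):
    """A CIGAR string is empty, ragged or uses an unsupported operation."""


class ModelError(FamvizError):
    """A gene/transcript/tree/track object violates a structural invariant."""
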