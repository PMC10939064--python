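"""Exception hierarchy.

InputError subclasses map to CLI exit code 2, MetadataError and
ReferenceError to exit code 3.
"""


class KneecartError(Exception):
    """Base class for all package errors."""


class InputError(KneecartError):
    """Bad or unreadable user input (masks, file pairing, formats)."""


class FormatError(InputError):
    """A file parsed but violates the expected format (e.g. zero-area image)."""


class MetadataError(KneecartError):
    """Required acquisition metadata missing or inconsistent."""


class EmptyMaskError(InputError):
    """A bone class has no foreground pixels after cleanup."""


class DegenerateGeometryError(InputError):
    """Measurement geometry cannot be constructed (e.g. coincident endpoints)."""


class AmbiguousCompartmentError(MetadataError):
    """Slice position does not determine the compartment and no override given."""


class ReferenceError_(KneecartError):
    """Reference-table problem: missing cells or non-positive standards."""
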