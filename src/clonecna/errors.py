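"""Exception hierarchy.

Two user-facing failure classes: malformed files (:class:`FormatError`) and
well-formed files carrying invalid values (:class:`ValidationError`).  The CLI
maps both to exit code 2; genuine I/O failures (missing file, unwritable
directory) surface as ``OSError`` and map to exit code 3.
"""


class CloneCnaError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(CloneCnaError):
    """A file does not follow its declared dialect (missing column, bad line)."""


class ValidationError(CloneCnaError):
    """Parsed values violate an invariant (negative TPM, overlapping segments, ...)."""
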