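"""Exception hierarchy shared by all modules.

Exit-code mapping used by the CLI: user/input/format/validation errors
exit 2; integrity errors (corrupted index files) exit 3.
"""


class CompoundMapError(Exception):
    """Base class for all package errors."""

    exit_code = 2


class InputError(CompoundMapError):
    """Bad user input: missing file, empty query, unknown identifier."""


class ValidationError(CompoundMapError):
    """Input parsed but violates a domain invariant (duplicate id, empty map)."""


class FormatError(CompoundMapError):
    """A file does not conform to its declared dialect or schema."""


class IntegrityError(CompoundMapError):
    """Paired index files contradict each other."""

    exit_code = 3
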