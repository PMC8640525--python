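"""Exception types shared across the package."""


class DegensimError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(DegensimError, ValueError):
    """A precondition on an operation's arguments was violated."""


class FormatError(DegensimError):
    """A serialized artifact is missing or malformed; the message names the field."""


class MissingResourceError(DegensimError, FileNotFoundError):
    """A required external resource (e.g. pretrained weights) was not supplied."""
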