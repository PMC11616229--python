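"""Exception hierarchy.

``UsageError`` maps to CLI exit code 2, the other two to exit code 1.
"""


class PhenovecError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(PhenovecError):
    """An input file could not be parsed (message names line/position)."""


class ValidationError(PhenovecError):
    """Parsed input violates a contract (missing/duplicate ids, bad weights...)."""


class UsageError(PhenovecError):
    """Mutually exclusive or otherwise contradictory options."""
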