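"""Exception hierarchy shared across the pipeline.

Two user-facing classes map onto the CLI exit-code contract:
``UsageError`` (bad invocation or parameters, exit 1) and ``FormatError``
(malformed input data, exit 2). Domain-level misuse of library functions
raises plain ``ValueError`` like the rest of the scientific stack.
"""


class WoundnetError(Exception):
    """Base class for errors raised by this package."""


class UsageError(WoundnetError):
    """The caller asked for something invalid (empty seed list, bad threshold)."""


class FormatError(WoundnetError):
    """An input file does not conform to its declared format."""
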