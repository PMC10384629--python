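"""Exception hierarchy.

``LucdesignError`` is the package base class. ``ValidationError`` marks
rejected input data (bad alphabet, malformed records, out-of-range
coordinates); the CLI maps it to exit code 2.
"""


class LucdesignError(Exception):
    """Base class for all package errors."""


class ValidationError(LucdesignError, ValueError):
    """Invalid input data or coordinates."""
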