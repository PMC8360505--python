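"""Exception hierarchy.

All data-facing failures raise :class:`WormwellError` subclasses so callers
(and the CLI) can distinguish validation problems from programming errors.
"""


class WormwellError(Exception):
    """Base class for all data/validation errors raised by this package."""


class FilenameParseError(WormwellError):
    """An image filename does not follow the {date}-{experiment}-{plate}-{magnification}_{well} grammar."""


class ValidationError(WormwellError):
    """An input table violates the canonical-table contract."""
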