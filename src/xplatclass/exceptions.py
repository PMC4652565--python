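"""Exception hierarchy.

All package-specific failures derive from :class:`XplatError` so callers
(and the CLI) can distinguish configuration problems from data problems.
"""


class XplatError(Exception):
    """Base class for all xplatclass errors."""


class FormatError(XplatError):
    """Structurally invalid input file (duplicate ids, bad header, ...)."""


class ParseError(XplatError):
    """A cell of an input file could not be parsed as the expected type."""


class LabelError(XplatError):
    """Unknown subtype token or degenerate label vector."""


class CoverageError(XplatError):
    """A label table does not cover every requested sample."""


class DomainError(XplatError):
    """A value lies outside the mathematical domain of an operation."""


class AlignmentError(XplatError):
    """Feature or sample identifiers do not line up between inputs."""


class SizeError(XplatError):
    """A requested size/count exceeds what the data can provide."""


class ConfigError(XplatError):
    """Invalid configuration value."""


class ContractError(XplatError):
    """A trained model was applied to data violating its training contract."""


class SplitError(XplatError):
    """A stratified split cannot be formed (class too small)."""
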