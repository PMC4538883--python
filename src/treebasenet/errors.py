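"""Exception types shared across the package."""


class TreebasenetError(Exception):
    """Base class for all package-specific errors."""


class ParseError(TreebasenetError):
    """Raised when a serialized network cannot be parsed.

    Carries ``line``/``column`` attributes when the position is known.
    """

    def __init__(self, message, line=None, column=None):
        super().__init__(message)
        self.line = line
        self.column = column


class FormatError(TreebasenetError):
    """Raised when a network cannot be written in the requested format."""


class InvalidNetworkError(TreebasenetError):
    """Raised when an operation requires a valid binary phylogenetic network.

    ``report`` holds the :class:`~treebasenet.network_core.ValidationReport`.
    """

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report


class GenerationError(TreebasenetError):
    """Raised when a random-network generator cannot satisfy its constraints."""
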