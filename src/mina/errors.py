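"""Exception types shared across the package."""


class MinaError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(MinaError):
    """A malformed input file; the message names the offending line."""
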