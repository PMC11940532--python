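"""Exception hierarchy.

``RamanidError`` is the root; user-facing code can catch it to distinguish
data/config problems from genuine bugs.
"""


class RamanidError(Exception):
    """Base class for all errors raised by ramanid."""


class ValidationError(RamanidError):
    """Input data violates a structural invariant (lengths, ordering, ranges)."""


class ParseError(RamanidError):
    """A text file could not be parsed; the message names the offending line."""


class ConfigError(RamanidError):
    """A configuration value is out of its legal range."""
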