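"""Exception hierarchy shared across the package."""


class QtstError(Exception):
    """Base class for all package-specific errors."""


class ParseError(QtstError):
    """Malformed input text (XYZ files, frequency sidecars, records)."""


class ValidationError(QtstError):
    """A domain object violates one of its invariants."""


class LeakageError(QtstError):
    """Hold-out data reached a fitting routine."""


class TruncationError(QtstError):
    """A state-sum oracle was truncated before convergence."""
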