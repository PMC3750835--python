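"""Exception hierarchy shared across the package."""


class CorrdiffError(Exception):
    """Base class for all errors raised by corrdiff."""


class ValidationError(CorrdiffError, ValueError):
    """A domain object or parameter violates one of its invariants."""


class FormatError(CorrdiffError, ValueError):
    """An on-disk file is malformed or inconsistent with its sidecar."""
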