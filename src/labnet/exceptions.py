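"""Exception types shared across the package."""


class LabnetError(ValueError):
    """Base class for all labnet errors."""


class FormatError(LabnetError):
    """A file could not be parsed (non-numeric cell, malformed edge list, ...)."""


class ValidationError(LabnetError):
    """Inputs violate a contract (duplicate ids, too few samples, bad config, ...)."""
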