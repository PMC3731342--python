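"""Exception hierarchy shared across the package."""


class CaprachronError(Exception):
    """Base class for package errors."""


class AlignmentError(CaprachronError):
    """Ragged or otherwise structurally invalid alignment."""


class ParseError(CaprachronError):
    """Malformed input file (offending record named in the message)."""


class DataQualityError(CaprachronError):
    """Biological sanity violation, e.g. an internal stop codon (numt signal)."""


class UsageError(CaprachronError):
    """Invalid arguments or preconditions."""


class ConvergenceError(CaprachronError):
    """Optimizer failed to converge after all restarts."""
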