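"""Exception hierarchy.

Everything raised deliberately by this package derives from :class:`DmcmcpError`
so callers (and the CLI) can distinguish usage problems from genuine bugs.
"""


class DmcmcpError(Exception):
    """Base class for all errors raised by dmcmcp."""


class InvalidArgumentError(DmcmcpError, ValueError):
    """A parameter value violates a documented precondition."""


class InvalidInputError(DmcmcpError, ValueError):
    """Input data (features, rasters, matrices) is malformed; names the offender."""


class InfeasibleMatchingError(DmcmcpError):
    """No b-regular graph exists for the requested (n, b)."""


class SizeLimitError(DmcmcpError):
    """Instance exceeds the documented limit of an exact/enumerative routine."""


class ConfigError(DmcmcpError):
    """Session or CLI configuration is inconsistent."""


class StuckProposalError(DmcmcpError):
    """Proposal redraw limit exhausted without finding a state distinct from x."""


class ReplayDesyncError(DmcmcpError):
    """Replay log disagrees with the pair the engine offered."""


class EndOfLogError(DmcmcpError):
    """Replay chooser ran out of recorded trials."""


class EmptySampleError(DmcmcpError):
    """No chain trials survive the requested burn-in."""


class TaggingError(DmcmcpError):
    """A chosen item has no category tag; carries the item id."""


class LogValidationError(DmcmcpError):
    """A trial log violates its structural invariants."""


class LogParseError(DmcmcpError):
    """A trial-log (or matrix/graph) file could not be parsed; carries a line number."""
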