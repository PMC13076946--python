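"""Exception hierarchy for geiprs.

Exit-code mapping used by the CLI: config errors -> 2, data/format
errors -> 3, numerical failures -> 4.
"""


class GeiprsError(Exception):
    """Base class for all geiprs errors."""


class InvalidConfigError(GeiprsError, ValueError):
    """A configuration value violates its documented constraints."""


class FormatError(GeiprsError, ValueError):
    """An input file does not conform to its format contract."""


class DegenerateInputError(GeiprsError, ValueError):
    """Input data is degenerate (zero variance, rank deficiency, ...)."""


class ConvergenceError(GeiprsError, RuntimeError):
    """A solver failed to reach its optimality tolerance."""

    def __init__(self, message: str, worst_kkt: float | None = None):
        super().__init__(message)
        self.worst_kkt = worst_kkt
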