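"""Exception hierarchy.

Validation problems (bad configuration, bad arguments) and data problems
(incomplete batteries, degenerate responses) are kept distinct so the CLI
can map them to exit codes 2 and 3 respectively.
"""


class NeuroasymError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NeuroasymError, ValueError):
    """Invalid configuration: non-finite values, negative SDs, unknown keys."""


class DomainError(NeuroasymError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class DataError(NeuroasymError):
    """Input data are structurally invalid or incomplete."""


class ProtocolError(DataError):
    """The stimulation battery is incomplete (missing ISI cells)."""

    def __init__(self, missing, message=None):
        self.missing = tuple(missing)
        super().__init__(message or f"battery incomplete; missing ISI cells: {self.missing}")


class WindowBoundsError(DataError):
    """A response window falls outside the recorded sweep."""


class DegenerateResponseError(DataError):
    """Unconditioned R2 amplitude is zero/negative: baseline unmeasurable."""


class UndefinedAsymmetryError(DataError):
    """Asymmetry index undefined because both sides are zero."""


class DegenerateROCError(DataError):
    """ROC analysis impossible: only one class present."""
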