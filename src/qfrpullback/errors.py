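"""Exception hierarchy for the pullback-analysis pipeline."""


class QfrPullbackError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(QfrPullbackError, ValueError):
    """A parameter is outside its admissible range."""


class InvalidTraceError(QfrPullbackError, ValueError):
    """A pullback trace violates its structural invariants."""


class TraceParseError(QfrPullbackError, ValueError):
    """A trace file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class OutOfRangeError(QfrPullbackError, ValueError):
    """A queried position lies outside the analyzed vessel."""


class NoFunctionalDiseaseError(QfrPullbackError, ValueError):
    """The vessel shows no measurable QFR decline, so pattern and QVP index
    are undefined (the study only analyzed functionally diseased vessels)."""


class DegenerateLabelsError(QfrPullbackError, ValueError):
    """A binary analysis was requested but only one outcome class is present."""


class CollinearityError(QfrPullbackError, ValueError):
    """The regression design matrix is singular."""


class GenerationError(QfrPullbackError, ValueError):
    """The requested synthetic-vessel parameters are infeasible."""
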