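"""Exception hierarchy for acquisition automation."""


class NmrbotError(Exception):
    """Base class for all package errors."""


class ManifestSyntaxError(NmrbotError):
    """Malformed STAR manifest text (bad loop/tag structure).

    Carries the 1-based line number where parsing failed.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ManifestValidationError(NmrbotError):
    """Semantically invalid manifest; carries the full validation report."""

    def __init__(self, report):
        self.report = report
        super().__init__(str(report))


class InstrumentContractError(NmrbotError):
    """A backend operation was called in a state that forbids it
    (e.g. acquire without an inserted sample or an established lock)."""


class LockError(NmrbotError):
    """Deuterium lock could not be established (unknown solvent).

    Recoverable: the engine logs it and skips the sample.
    """


class UnknownParameterSetError(NmrbotError):
    """Requested experiment parameter-set name is not in the library."""


class NoSolventPeakError(NmrbotError):
    """Solvent-offset detection found no peak to report."""


class GainClippedAtMinimumError(NmrbotError):
    """Even the minimum receiver gain clips the digitizer."""

    def __init__(self, min_gain: float):
        self.min_gain = min_gain
        super().__init__(
            f"signal clips even at minimum receiver gain {min_gain}"
        )


class WizardAborted(NmrbotError):
    """User quit the setup wizard; nothing was written."""
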