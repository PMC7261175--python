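"""Exception and warning types shared across the pipeline."""


class SmFretError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(SmFretError, ValueError):
    """A model or generator parameter is outside its valid range."""


class FormatError(SmFretError, ValueError):
    """A trace file does not conform to the documented dialect."""


class CorruptFileError(FormatError):
    """A binary trace file is truncated or internally inconsistent."""


class TooShortError(SmFretError, ValueError):
    """A series is shorter than the minimum analyzable length."""


class ZeroVarianceError(SmFretError, ValueError):
    """Correlation is undefined because a channel has zero variance."""


class EmptySeriesError(SmFretError, ValueError):
    """No valid FRET frames remain after truncation and exclusion."""


class UnclassifiableError(SmFretError, ValueError):
    """Too few valid frames to decide static vs dynamic."""


class EmptyHistogramError(SmFretError, ValueError):
    """No frames available to histogram."""


class FitError(SmFretError, RuntimeError):
    """A nonlinear fit failed to converge; carries residual diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class UnresolvableKdError(FitError):
    """The titration response is too flat to constrain a dissociation constant."""


class InvalidSpectrumError(SmFretError, ValueError):
    """Absorbance spectrum is inconsistent (e.g. corrected A280 <= 0)."""


class InsufficientReplicatesError(SmFretError, ValueError):
    """Fewer than two replicate values in a group to be compared."""


class PipelineError(SmFretError, RuntimeError):
    """A pipeline stage failed; names the stage and condition."""


class DegenerateSignalWarning(UserWarning):
    """The simulated response carries no signal (e.g. r_bound == r_free)."""
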