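"""Exception hierarchy shared across the pipeline stages."""


class RedoxScreenError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(RedoxScreenError, ValueError):
    """An operation received an out-of-range or inconsistent parameter."""


class InterfaceError(RedoxScreenError, ValueError):
    """Mismatched array shapes / bin counts between collaborating objects."""


class DesignError(RedoxScreenError, ValueError):
    """Invalid plate design (duplicate keys, bad trajectory, ...)."""


class GenerationError(RedoxScreenError, RuntimeError):
    """Synthetic data could not be generated under the requested geometry."""


class MaskingError(RedoxScreenError, RuntimeError):
    """No foreground separable from background during cell masking."""


class MeasurementError(RedoxScreenError, RuntimeError):
    """Intensity measurement impossible (e.g. empty mask)."""


class BackgroundError(RedoxScreenError, RuntimeError):
    """Not enough cell-free area for automatic background ROI selection."""


class NormalizationError(RedoxScreenError, ValueError):
    """Zero or negative background intensity in the ORR normalization."""


class JoinError(RedoxScreenError, ValueError):
    """A record could not be resolved against the plate design."""


class ComparisonError(RedoxScreenError, ValueError):
    """A statistical comparison was requested on insufficient data."""


class StageError(RedoxScreenError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original}")
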