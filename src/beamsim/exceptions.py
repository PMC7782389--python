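"""Exception hierarchy for beamsim.

All package-specific failures derive from :class:`BeamsimError` so callers
can catch simulation problems without swallowing programming errors.
"""


class BeamsimError(Exception):
    """Base class for all beamsim errors."""


class InvalidArgumentError(BeamsimError, ValueError):
    """An argument violates a documented precondition."""


class ConfigError(InvalidArgumentError):
    """A simulation configuration failed validation."""


class StabilityError(BeamsimError, RuntimeError):
    """No stable MVAR model could be generated within the iteration budget."""


class DegenerateInputError(BeamsimError, ValueError):
    """An input is degenerate (zero power, constant row, ...)."""


class GeometryError(BeamsimError, ValueError):
    """Electrode/source geometry is unusable (e.g. coincident points)."""


class RankError(BeamsimError, ValueError):
    """A lead-field (or stacked constraint matrix) is rank deficient."""


class SingularFrequencyError(BeamsimError, ValueError):
    """The spectral MVAR matrix is singular at some frequency."""

    def __init__(self, freq: float):
        self.freq = float(freq)
        super().__init__(f"spectral MVAR matrix singular at normalized frequency {freq}")


class ConditioningError(BeamsimError, RuntimeError):
    """A regression or inversion failed due to ill-conditioning."""


class PipelineError(BeamsimError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original}")
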