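"""Exception hierarchy."""


class DielgemError(Exception):
    """Base class for all package errors."""


class ModelValidationError(DielgemError):
    """A model violates a structural invariant; carries the violation list."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__(
            "model failed validation:\n  " + "\n  ".join(self.violations)
        )


class SBMLError(DielgemError):
    """SBML parse or serialization failure."""


class PipelineError(DielgemError):
    """A diel transformation step could not be applied."""


class SimulationError(DielgemError):
    """FBA / validation quantity could not be computed."""


class DFAError(DielgemError):
    """Sampling or differential-flux analysis failure."""
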