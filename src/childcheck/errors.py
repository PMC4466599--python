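"""Exception hierarchy shared across the package."""


class ValidationError(ValueError):
    """Input violates a documented precondition (named field in the message)."""


class OutOfRangeError(ValidationError):
    """A requested age lies outside the growth reference's tabulated range."""


class ConfigurationError(ValueError):
    """A configuration document (ruleset, offsets map, cohort config) is invalid."""


class SeparationError(RuntimeError):
    """Logistic fit failed because a covariate perfectly separates the outcome."""

    def __init__(self, covariates, message=None):
        self.covariates = list(covariates)
        super().__init__(
            message
            or "perfect separation detected; offending covariate(s): "
            + ", ".join(self.covariates)
        )


class UnsatisfiableConfigError(ConfigurationError):
    """A cohort configuration cannot be realised (e.g. prevalence 0 or 1)."""


class ConsultationError(RuntimeError):
    """A consultation section failed; no partial report is emitted.

    ``section`` names the failing step: ``weight``, ``risk`` or ``lifestyle``.
    """

    def __init__(self, section, cause):
        self.section = section
        self.cause = cause
        super().__init__(f"[{section}] {cause}")
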